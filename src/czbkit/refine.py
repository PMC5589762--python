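"""Ensemble refinement: energy/violation filtering and centroid extraction.

Snapshots are filtered sequentially: first by keeping the lowest percentile
of each named energy annotation, then by a cap on the per-structure mean
restraint violation.  The per-structure statistic (plain average of
one-sided violations in that snapshot) is the filtering score; the r⁻⁶
ensemble-averaged statistic is reserved for reporting on the final
ensemble, since it is not defined per member.

Centroids are extracted by PAM k-medoids (BUILD + SWAP) on a pairwise
superposed-RMSD matrix; ties break to the lowest index, so the procedure is
deterministic for a given matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, SelectionError
from .restraints import RestraintSet, structure_mean_violation
from .structio import AtomSelector, Ensemble, superpose


@dataclass
class FilterSpec:
    """Refinement thresholds.

    ``energy_percentile_keep`` retains the lowest x% for each annotation in
    ``energy_keys``, applied sequentially; ``violation_max`` (Å) then caps
    the per-structure mean violation.  Defaults are documented placeholders
    exposed here because published refinement protocols rarely state their
    cutoffs.
    """

    energy_percentile_keep: float = 50.0
    violation_max: float = 0.5
    energy_keys: tuple[str, ...] = ("energy",)

    def __post_init__(self):
        if not (0 < self.energy_percentile_keep <= 100):
            raise ValueError("energy_percentile_keep must be in (0, 100]")
        if self.violation_max < 0:
            raise ValueError("violation_max must be >= 0")


@dataclass
class FilterReport:
    n_input: int
    removed_per_criterion: dict[str, int]
    kept_indices: list[int]

    @property
    def n_kept(self) -> int:
        return len(self.kept_indices)


def filter_ensemble(
    ensemble: Ensemble,
    restraint_set: RestraintSet | None,
    spec: FilterSpec | None = None,
    violation_subset: str = "all",
) -> tuple[Ensemble, FilterReport]:
    """Refine an annotated ensemble; original member order is preserved."""
    spec = spec or FilterSpec()
    keep = np.arange(len(ensemble))
    removed: dict[str, int] = {}
    for key in spec.energy_keys:
        if key not in ensemble.annotations:
            raise ContractError(f"ensemble lacks required annotation {key!r}")
        values = ensemble.annotations[key][keep]
        cutoff = np.percentile(values, spec.energy_percentile_keep)
        mask = values <= cutoff
        removed[key] = int((~mask).sum())
        keep = keep[mask]
        if len(keep) == 0:
            raise SelectionError(
                f"all members removed; per-criterion removals: {removed}"
            )
    if restraint_set is not None and np.isfinite(spec.violation_max):
        viol = np.array(
            [
                structure_mean_violation(
                    ensemble.members[i], restraint_set, violation_subset
                )
                for i in keep
            ]
        )
        mask = viol <= spec.violation_max
        removed["violation"] = int((~mask).sum())
        keep = keep[mask]
    if len(keep) == 0:
        raise SelectionError(
            f"all members removed; per-criterion removals: {removed}"
        )
    report = FilterReport(
        n_input=len(ensemble),
        removed_per_criterion=removed,
        kept_indices=[int(i) for i in keep],
    )
    return ensemble.subset(report.kept_indices), report


def pairwise_rmsd_matrix(
    ensemble: Ensemble, selector: AtomSelector | None = None
) -> np.ndarray:
    """Symmetric matrix of pairwise superposed RMSDs over a selection."""
    if len(ensemble) < 2:
        raise ContractError("need at least 2 members for a pairwise matrix")
    selector = selector or AtomSelector()
    if len(selector.indices(ensemble.members[0])) == 0:
        raise SelectionError("clustering selector resolves to no atoms")
    n = len(ensemble)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, r = superpose(ensemble.members[i], ensemble.members[j], selector)
            mat[i, j] = mat[j, i] = r
    return mat


@dataclass
class CentroidReport:
    centroid_indices: list[int]
    assignment: np.ndarray  # cluster label per member (index into centroids)
    objective: float  # summed within-cluster distance to medoid

    @property
    def k(self) -> int:
        return len(self.centroid_indices)


def extract_centroids(
    matrix: np.ndarray, k: int = 6, seed: int = 0
) -> CentroidReport:
    """PAM k-medoids on a distance matrix (deterministic BUILD + SWAP).

    ``seed`` is accepted for interface stability; BUILD initialisation makes
    the procedure deterministic without it.  Ties break to the lowest index.
    """
    matrix = np.asarray(matrix, float)
    n = matrix.shape[0]
    if matrix.shape != (n, n):
        raise ContractError("distance matrix must be square")
    if k > n:
        raise ContractError(f"k={k} exceeds {n} members")
    if k == n:
        medoids = list(range(n))
    else:
        # BUILD: greedy seeding
        medoids = [int(np.argmin(matrix.sum(axis=1)))]
        while len(medoids) < k:
            current = matrix[:, medoids].min(axis=1)
            gains = np.array(
                [
                    np.maximum(current - matrix[:, c], 0.0).sum()
                    if c not in medoids
                    else -np.inf
                    for c in range(n)
                ]
            )
            medoids.append(int(np.argmax(gains)))
        # SWAP: steepest-descent swaps until no improvement
        def objective(meds: list[int]) -> float:
            return float(matrix[:, meds].min(axis=1).sum())

        best = objective(medoids)
        improved = True
        while improved:
            improved = False
            for mi, m in enumerate(sorted(medoids)):
                meds = sorted(medoids)
                for c in range(n):
                    if c in meds:
                        continue
                    trial = meds.copy()
                    trial[meds.index(m)] = c
                    obj = objective(trial)
                    if obj < best - 1e-12:
                        best, medoids, improved = obj, trial, True
                        break
                if improved:
                    break
    medoids = sorted(int(m) for m in medoids)
    assignment = np.argmin(matrix[:, medoids], axis=1)
    # members equidistant to several medoids go to the lowest medoid index,
    # which argmin already guarantees; medoids assign to themselves
    for ci, m in enumerate(medoids):
        assignment[m] = ci
    objective_val = float(
        sum(matrix[i, medoids[assignment[i]]] for i in range(n))
    )
    return CentroidReport(medoids, assignment, objective_val)


def centroid_ensemble(
    ensemble: Ensemble,
    k: int = 6,
    selector: AtomSelector | None = None,
    seed: int = 0,
) -> tuple[Ensemble, CentroidReport]:
    """Convenience: RMSD matrix + k-medoids + centroid sub-ensemble."""
    mat = pairwise_rmsd_matrix(ensemble, selector)
    report = extract_centroids(mat, k=k, seed=seed)
    return ensemble.subset(report.centroid_indices), report
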