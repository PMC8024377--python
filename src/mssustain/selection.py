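"""Subtype-count selection by leave-one-dataset-out cross-validation and
cross-fold posterior agreement.

Each contributing study (dataset) is held out once; models with 1..C_max
subtypes are fitted on the remaining datasets and scored by the total
mixture log-likelihood of the held-out dataset.  The subtype count that
maximises the summed held-out log-likelihood is selected (ties go to the
smaller count) and the final model is refitted on all datasets.  Agreement
of the posterior sequence distributions across folds is quantified with
the Bhattacharyya coefficient (0 = no overlap, 1 = identical), averaged
over events after aligning subtypes between folds.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sustain import (
    EventGrid,
    McmcSamples,
    SubtypeModel,
    SustainOptions,
    fit_sustain_path,
    mcmc_sample,
    positional_distribution,
    total_loglik,
)

__all__ = [
    "FoldSpec",
    "CvResult",
    "AgreementReport",
    "split_by_dataset",
    "cv_select_subtypes",
    "bhattacharyya",
    "cross_fold_agreement",
]


@dataclass(frozen=True)
class FoldSpec:
    """Leave-one-dataset-out folds: (training ids, held-out id) pairs, one
    per dataset, ordered by held-out id."""

    folds: tuple[tuple[tuple[str, ...], str], ...]

    def __len__(self) -> int:
        return len(self.folds)

    def __iter__(self):
        return iter(self.folds)


def split_by_dataset(table: pd.DataFrame, dataset_col: str = "dataset_id"
                     ) -> FoldSpec:
    """One fold per dataset id, deterministically ordered by id."""
    ids = sorted(map(str, pd.unique(table[dataset_col].astype(str))))
    if len(ids) < 2:
        raise ValueError("leave-one-dataset-out needs at least 2 datasets")
    folds = tuple(
        (tuple(d for d in ids if d != held), held) for held in ids
    )
    return FoldSpec(folds)


@dataclass
class CvResult:
    """Held-out log-likelihood table and the selected subtype count."""

    table: pd.DataFrame  # index = held-out id, columns = candidate C
    selected: int
    final_model: SubtypeModel
    fold_models: dict[str, list[SubtypeModel]]
    fold_samples: dict[str, McmcSamples] = field(default_factory=dict)

    def summed(self) -> pd.Series:
        return self.table.sum(axis=0)


def cv_select_subtypes(
    Z: pd.DataFrame,
    grid: EventGrid,
    folds: FoldSpec | None = None,
    candidates=(1, 2, 3, 4),
    opts: SustainOptions | None = None,
    mcmc_iterations: int = 0,
    dataset_col: str = "dataset_id",
) -> CvResult:
    """Leave-one-dataset-out selection of the number of subtypes.

    For every fold and candidate count, fits the model hierarchically on
    the training datasets and evaluates the held-out dataset's total
    log-likelihood; selects the argmax of the fold-summed held-out
    log-likelihood (ties to the smaller count) and refits on all data.
    With ``mcmc_iterations > 0``, posterior sequence samples are drawn per
    fold at the selected count (for cross-fold agreement).
    """
    opts = opts or SustainOptions()
    if folds is None:
        folds = split_by_dataset(Z, dataset_col)
    candidates = sorted(int(c) for c in candidates)
    if candidates[0] < 1:
        raise ValueError("candidate subtype counts must be >= 1")
    cmax = candidates[-1]
    ds = Z[dataset_col].astype(str)

    table = pd.DataFrame(index=[held for _, held in folds],
                         columns=candidates, dtype=float)
    fold_models: dict[str, list[SubtypeModel]] = {}
    for train_ids, held in folds:
        train = Z[ds.isin(train_ids)]
        test = Z[ds == held]
        try:
            path = fit_sustain_path(train, grid, cmax, opts)
        except Exception as exc:  # record and exclude the fold
            warnings.warn(f"fold {held}: fit failed ({exc}); excluded",
                          stacklevel=2)
            continue
        fold_models[held] = path
        for c in candidates:
            table.loc[held, c] = total_loglik(test, path[c - 1])
    if table.isna().all(axis=None):
        raise RuntimeError("every cross-validation fold failed")
    summed = table.sum(axis=0)
    selected = int(summed.idxmax())  # ties resolve to the smaller C (sorted)

    final_path = fit_sustain_path(Z, grid, selected, opts)
    result = CvResult(table=table, selected=selected,
                      final_model=final_path[-1], fold_models=fold_models)
    if mcmc_iterations > 0:
        for i, (train_ids, held) in enumerate(folds):
            model = fold_models.get(held)
            if model is None:
                continue
            train = Z[ds.isin(train_ids)]
            seed = None if opts.seed is None else opts.seed + 1000 + i
            result.fold_samples[held] = mcmc_sample(
                train, model[selected - 1], iterations=mcmc_iterations,
                seed=seed)
    return result


def bhattacharyya(p, q) -> float:
    """Bhattacharyya coefficient sum_i sqrt(p_i q_i) between two discrete
    distributions on the same support."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must share the same support")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("negative probabilities")
    if abs(p.sum() - 1.0) > 1e-9 or abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("inputs must each sum to 1")
    return float(np.sqrt(p * q).sum())


@dataclass
class AgreementReport:
    """Cross-fold sequence-posterior agreement per subtype."""

    mean: np.ndarray  # (C,) mean Bhattacharyya coefficient over fold pairs
    sd: np.ndarray
    alignments: dict  # (fold_a, fold_b) -> tuple permutation of subtypes
    per_pair: pd.DataFrame


def _pair_agreement(P_a: list[np.ndarray], P_b: list[np.ndarray],
                    perm: tuple[int, ...]) -> np.ndarray:
    """Per-subtype mean-over-events Bhattacharyya for one alignment."""
    C = len(P_a)
    out = np.empty(C)
    for c in range(C):
        A, B = P_a[c], P_b[perm[c]]
        out[c] = np.mean([bhattacharyya(A[e], B[e]) for e in range(A.shape[0])])
    return out


def cross_fold_agreement(fold_samples: dict | list, selected_c: int
                         ) -> AgreementReport:
    """Align subtypes between every fold pair (exhaustive bijection search)
    and report the mean +/- SD of event-averaged Bhattacharyya
    coefficients per subtype."""
    if isinstance(fold_samples, dict):
        items = sorted(fold_samples.items())
    else:
        items = list(enumerate(fold_samples))
    if len(items) < 2:
        raise ValueError("need samples from at least two folds")
    grids = {s.grid for _, s in items}
    if len(grids) != 1:
        raise ValueError("fold samples use differing event grids")
    pos = {
        name: [positional_distribution(s, c) for c in range(selected_c)]
        for name, s in items
    }
    names = [name for name, _ in items]
    rows, alignments = [], {}
    per_subtype: list[list[float]] = [[] for _ in range(selected_c)]
    for a, b in itertools.combinations(names, 2):
        best_perm, best_val, best_per = None, -np.inf, None
        for perm in itertools.permutations(range(selected_c)):
            vals = _pair_agreement(pos[a], pos[b], perm)
            if vals.mean() > best_val:
                best_perm, best_val, best_per = perm, vals.mean(), vals
        alignments[(a, b)] = best_perm
        rows.append({"fold_a": a, "fold_b": b,
                     **{f"subtype_{c}": best_per[c] for c in range(selected_c)}})
        for c in range(selected_c):
            per_subtype[c].append(best_per[c])
    arr = np.array(per_subtype)  # (C, n_pairs)
    return AgreementReport(
        mean=arr.mean(axis=1),
        sd=arr.std(axis=1, ddof=1) if arr.shape[1] > 1 else np.zeros(selected_c),
        alignments=alignments,
        per_pair=pd.DataFrame(rows),
    )
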