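"""Positive-predictive-value evaluation over repeated train/test partitions.

The core evaluation engine: the sample set is split 50/50 into a training
and a test half (50 independent partitions by default, stratified so the
two halves have matched phenotype composition).  Features are selected on
the training half with one of WF/VF/SPCA; a selected CpG counts as a *true
positive* if it reaches p < 0.05 in the matched test half with the same
direction of change.  The PPV of an evaluation set (the top 50, 100, ...,
1500 training-ranked CpGs) is the fraction of its members that are true
positives.

Under pure noise the expected PPV is 0.025: a null CpG passes the test-set
screen with probability 0.05 (two-sided) and agrees in direction with
probability 1/2.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    MethylationMatrix,
    PartitionSet,
    Phenotype,
    PPVMatrix,
    RankedFeatureList,
)
from .quantify import convert_measure
from .selection import compute_association, select_features

DEFAULT_SIZES = tuple(range(50, 1550, 50))
DEFAULT_N_PARTITIONS = 50
TEST_P_CUT = 0.05


# ---------------------------------------------------------------------------
# Partitions
# ---------------------------------------------------------------------------

def _split_ids_half(ids: np.ndarray, rng: np.random.Generator):
    """Shuffle, drop one surplus sample if the count is odd, split in half."""
    ids = rng.permutation(ids)
    if len(ids) % 2 == 1:
        ids = ids[:-1]
    half = len(ids) // 2
    return ids[:half], ids[half:]


def make_partitions(
    phenotype: Phenotype,
    n_partitions: int = DEFAULT_N_PARTITIONS,
    seed: int = 0,
    n_strata: int = 4,
) -> PartitionSet:
    """Repeated stratified 50/50 train/test splits.

    Binary phenotypes are stratified by class; continuous phenotypes by
    quantile bins (quartiles by default), so training and test halves have
    matched demographics.  Equal train/test sizes are enforced by dropping
    at most one (randomly chosen, per partition) surplus sample per
    stratum.  Deterministic given the seed.
    """
    if len(phenotype.sample_ids) < 4:
        raise ValueError("need at least 4 samples")
    ids = np.asarray(phenotype.sample_ids)
    values = phenotype.values.to_numpy()
    if phenotype.kind == "binary":
        strata = [ids[values == c] for c in (0, 1)]
        if min(len(s) for s in strata) < 2:
            raise ValueError("need at least 2 samples per class")
    else:
        edges = np.quantile(values, np.linspace(0, 1, n_strata + 1)[1:-1])
        bins = np.searchsorted(edges, values, side="left")
        strata = [ids[bins == b] for b in range(n_strata) if np.any(bins == b)]
    rng = np.random.default_rng(seed)
    partitions = []
    for _ in range(n_partitions):
        train, test = [], []
        for stratum in strata:
            tr, te = _split_ids_half(stratum, rng)
            train.extend(tr)
            test.extend(te)
        partitions.append((sorted(train), sorted(test)))
    return PartitionSet(partitions, seed)


def make_small_partitions(
    phenotype: Phenotype,
    n_per_class: int,
    n_partitions: int = DEFAULT_N_PARTITIONS,
    seed: int = 0,
) -> PartitionSet:
    """Disjoint train/test subsamples of ``n_per_class`` samples per class,
    for the small-sample-size evaluation regime."""
    if phenotype.kind != "binary":
        raise ValueError("small-sample evaluation requires a binary phenotype")
    ids = np.asarray(phenotype.sample_ids)
    values = phenotype.values.to_numpy()
    per_class = [ids[values == c] for c in (0, 1)]
    for cls in per_class:
        if len(cls) < 2 * n_per_class:
            raise ValueError(
                f"need {2 * n_per_class} samples per class for disjoint "
                f"train/test subsets, found {len(cls)}"
            )
    rng = np.random.default_rng(seed)
    partitions = []
    for _ in range(n_partitions):
        train, test = [], []
        for cls in per_class:
            picked = rng.choice(cls, size=2 * n_per_class, replace=False)
            train.extend(picked[:n_per_class])
            test.extend(picked[n_per_class:])
        partitions.append((sorted(train), sorted(test)))
    return PartitionSet(partitions, seed)


# ---------------------------------------------------------------------------
# True-positive counting and PPV curves
# ---------------------------------------------------------------------------

def count_true_positives(
    train_list: RankedFeatureList, test_assoc: pd.DataFrame, set_size: int
) -> int:
    """Among the top ``set_size`` training-ranked CpGs, count those with
    test p < 0.05 and the same direction of change as in training."""
    if set_size > len(train_list):
        raise ValueError("set_size exceeds the ranked list length")
    top_ids = train_list.feature_ids[:set_size]
    train_dir = train_list.directions[:set_size]
    present = test_assoc.index.get_indexer(top_ids)
    missing = present < 0
    if missing.any():
        warnings.warn(f"{int(missing.sum())} selected CpGs absent from the test table")
    p = np.full(set_size, np.nan)
    d = np.zeros(set_size)
    ok = ~missing
    p[ok] = test_assoc["p"].to_numpy()[present[ok]]
    d[ok] = test_assoc["direction"].to_numpy()[present[ok]]
    hits = (p < TEST_P_CUT) & (d == train_dir) & ok
    return int(hits.sum())


def ppv_curve(
    matrix: MethylationMatrix,
    phenotype: Phenotype,
    method: str = "WF",
    measure: str = "beta",
    statistic: str = "t",
    sizes=DEFAULT_SIZES,
    partitions: PartitionSet | None = None,
    n_partitions: int = DEFAULT_N_PARTITIONS,
    seed: int = 0,
    k: int = 1500,
) -> PPVMatrix:
    """PPV matrix (evaluation-set size x partition) for one method/measure.

    For each partition the training associations are computed, the chosen
    selection method is run, the test associations are computed with the
    same statistic, and PPV = true positives / evaluated size is recorded
    for every evaluation-set size.  Sizes beyond the selected-list length
    are evaluated over the full list and flagged in ``truncated_sizes``.
    """
    if statistic == "moderated_t" and phenotype.kind != "binary":
        raise ValueError("moderated_t requires a binary phenotype")
    work = convert_measure(matrix, measure)
    if partitions is None:
        partitions = make_partitions(phenotype, n_partitions, seed)
    sizes = list(sizes)
    out = np.full((len(sizes), partitions.n_partitions), np.nan)
    truncated = set()
    for j, (train_ids, test_ids) in enumerate(partitions):
        try:
            train_m = work.subset_samples(train_ids)
            test_m = work.subset_samples(test_ids)
            train_ph = phenotype.subset(train_ids)
            test_ph = phenotype.subset(test_ids)
            train_assoc = compute_association(train_m, train_ph, statistic)
            ranked = select_features(
                method, train_m, train_ph, k=k, statistic=statistic, assoc=train_assoc
            )
            test_assoc = compute_association(test_m, test_ph, statistic)
            for i, size in enumerate(sizes):
                eval_size = min(size, len(ranked))
                if eval_size == 0:
                    continue
                if eval_size < size:
                    truncated.add(size)
                tp = count_true_positives(ranked, test_assoc, eval_size)
                out[i, j] = tp / eval_size
        except Exception as exc:  # annotate failures with the partition index
            raise RuntimeError(f"partition {j} failed: {exc}") from exc
    values = pd.DataFrame(out, index=pd.Index(sizes, name="size"), columns=range(partitions.n_partitions))
    values = values.dropna(axis=0, how="all")
    return PPVMatrix(values, method, measure, statistic, truncated)


def small_sample_ppv(
    matrix: MethylationMatrix,
    phenotype: Phenotype,
    n_per_class: int,
    method: str = "WF",
    measure: str = "beta",
    sizes=DEFAULT_SIZES,
    n_partitions: int = DEFAULT_N_PARTITIONS,
    seed: int = 0,
    k: int = 1500,
) -> PPVMatrix:
    """PPV evaluation in the small-sample regime (2-3 samples per class).

    Training and test sets are disjoint ``n_per_class``-per-class
    subsamples and the statistic is forced to the moderated t, since the
    ordinary t is unusable at these sample sizes.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be at least 2")
    partitions = make_small_partitions(phenotype, n_per_class, n_partitions, seed)
    return ppv_curve(
        matrix,
        phenotype,
        method=method,
        measure=measure,
        statistic="moderated_t",
        sizes=sizes,
        partitions=partitions,
        k=k,
    )


# ---------------------------------------------------------------------------
# Comparisons and evaluation-set-size choice
# ---------------------------------------------------------------------------

@dataclass
class PPVComparison:
    p_value: float
    median_a: float
    median_b: float
    statistic: float


def compare_ppv(ppv_a, ppv_b, alternative: str = "two-sided", paired: bool = False) -> PPVComparison:
    """Wilcoxon comparison of two PPV samples (one row of two PPV matrices).

    By default an unpaired rank-sum (Mann-Whitney) test is used; set
    ``paired=True`` for a signed-rank test exploiting the shared
    partitions.
    """
    a = np.asarray(ppv_a, dtype=float)
    b = np.asarray(ppv_b, dtype=float)
    if paired and a.size != b.size:
        raise ValueError("paired comparison needs equal lengths")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return PPVComparison(1.0, float(np.median(a)), float(np.median(b)), np.nan)
    if paired:
        res = stats.wilcoxon(a, b, alternative=alternative, zero_method="wilcox")
    else:
        res = stats.mannwhitneyu(a, b, alternative=alternative)
    return PPVComparison(
        float(res.pvalue), float(np.median(a)), float(np.median(b)), float(res.statistic)
    )


def choose_evaluation_sizes(
    curves: dict,
    min_size: int | None = None,
    max_size: int | None = None,
    exhaustive_limit: int = 200_000,
) -> dict:
    """Pick one evaluation-set size per study so PPVs match across studies.

    ``curves`` maps a study name to its mean-PPV-vs-size curve (a Series
    indexed by size).  The chosen sizes minimise the variance of the
    resulting between-study PPV values, subject to the size constraints;
    ties go to smaller sizes.  The search is exhaustive over the size grid
    when the product of grid lengths is tractable, otherwise coordinate
    descent from the per-study sizes closest to the global mean PPV.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 studies")
    studies = sorted(curves)
    grids = {}
    for name in studies:
        curve = curves[name]
        sizes = np.asarray(curve.index)
        keep = np.ones(sizes.size, dtype=bool)
        if min_size is not None:
            keep &= sizes >= min_size
        if max_size is not None:
            keep &= sizes <= max_size
        if not keep.any():
            raise ValueError(f"no feasible evaluation sizes for study {name!r}")
        grids[name] = curve.iloc[np.flatnonzero(keep)].sort_index()

    def objective(choice):
        vals = np.array([grids[name].loc[choice[name]] for name in studies])
        return float(np.var(vals))

    n_comb = int(np.prod([len(grids[name]) for name in studies]))
    if n_comb <= exhaustive_limit:
        best, best_obj = None, np.inf
        for combo in itertools.product(*(grids[name].index for name in studies)):
            choice = dict(zip(studies, combo))
            obj = objective(choice)
            if obj < best_obj - 1e-15:
                best, best_obj = choice, obj
        return best
    # coordinate descent, initialised at the size closest to the global mean
    target = np.mean([g.mean() for g in grids.values()])
    choice = {
        name: g.index[int(np.argmin(np.abs(g.to_numpy() - target)))]
        for name, g in grids.items()
    }
    for _ in range(100):
        changed = False
        for name in studies:
            best_size, best_obj = choice[name], objective(choice)
            for size in grids[name].index:
                trial = dict(choice, **{name: size})
                obj = objective(trial)
                if obj < best_obj - 1e-15 or (
                    abs(obj - best_obj) <= 1e-15 and size < best_size
                ):
                    best_size, best_obj = size, obj
            if best_size != choice[name]:
                choice[name] = best_size
                changed = True
        if not changed:
            break
    return choice
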