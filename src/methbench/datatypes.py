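"""Shared containers for methylation benchmarking.

All matrices are CpG x sample pandas DataFrames: the row index holds CpG
identifiers, the columns hold sample identifiers.  Thin dataclasses tag the
raw frames with the semantics downstream code needs (which methylation
measure a matrix is on, whether a phenotype is binary or continuous).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

VALID_MEASURES = ("beta", "M")

#: columns of an association table (one row per CpG)
ASSOC_COLUMNS = ("stat", "p", "q", "direction", "mean_diff", "var", "df")


@dataclass
class MethylationMatrix:
    """A CpG x sample methylation matrix tagged with its measure.

    ``measure`` is ``"beta"`` (fraction methylated, values in [0, 1)) or
    ``"M"`` (log2 methylated/unmethylated ratio, any finite real).
    """

    values: pd.DataFrame
    measure: str

    def __post_init__(self) -> None:
        if self.measure not in VALID_MEASURES:
            raise ValueError(f"measure must be one of {VALID_MEASURES}, got {self.measure!r}")
        if not self.values.index.is_unique:
            raise ValueError("duplicate CpG identifiers")
        arr = self.values.to_numpy()
        if self.measure == "beta":
            if np.nanmin(arr) < 0 or np.nanmax(arr) >= 1:
                raise ValueError("beta values must lie in [0, 1)")
        elif not np.all(np.isfinite(arr)):
            raise ValueError("M values must be finite")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationMatrix":
        return MethylationMatrix(self.values.loc[:, list(sample_ids)], self.measure)


@dataclass
class IntensityPair:
    """Paired methylated/unmethylated fluorescence intensities.

    Intensities may be negative after background subtraction; the
    quantification formulas clamp them at zero.
    """

    methy: pd.DataFrame
    unmethy: pd.DataFrame

    def __post_init__(self) -> None:
        if self.methy.shape != self.unmethy.shape:
            raise ValueError("methy/unmethy shapes differ")
        if not self.methy.index.equals(self.unmethy.index) or not self.methy.columns.equals(
            self.unmethy.columns
        ):
            raise ValueError("methy/unmethy feature or sample IDs are not aligned")

    @property
    def feature_ids(self) -> pd.Index:
        return self.methy.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.methy.columns


@dataclass
class Phenotype:
    """Per-sample phenotype: binary class labels (0/1) or a continuous trait."""

    values: pd.Series
    kind: str  # "binary" | "continuous"

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous"):
            raise ValueError(f"kind must be 'binary' or 'continuous', got {self.kind!r}")
        if self.kind == "binary":
            classes = set(pd.unique(self.values))
            if not classes <= {0, 1}:
                raise ValueError("binary phenotype must be coded 0/1")
            if len(classes) < 2:
                raise ValueError("binary phenotype must contain both classes")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    def subset(self, sample_ids: Sequence[str]) -> "Phenotype":
        return Phenotype(self.values.loc[list(sample_ids)], self.kind)


@dataclass
class SyntheticTruth:
    """Ground truth of a simulation: signed target effect per associated CpG."""

    effects: pd.Series  # index: truth CpG ids; values: signed effect size

    @property
    def true_feature_ids(self) -> pd.Index:
        return self.effects.index

    @property
    def directions(self) -> pd.Series:
        return np.sign(self.effects)


class PriorEstimate(NamedTuple):
    """Empirical-Bayes variance prior: prior df ``d0`` (may be inf) and prior
    variance ``s0_squared``."""

    d0: float
    s0_squared: float


@dataclass
class RankedFeatureList:
    """Output of a feature-selection procedure: CpGs ordered best-first."""

    feature_ids: list
    scores: np.ndarray
    directions: np.ndarray
    method: str  # "WF" | "VF" | "SPCA"

    def __post_init__(self) -> None:
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature IDs in ranked list")

    def __len__(self) -> int:
        return len(self.feature_ids)

    def top(self, k: int) -> list:
        return self.feature_ids[:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.feature_ids) + 1),
                "cpg": self.feature_ids,
                "score": self.scores,
                "direction": self.directions,
                "method": self.method,
            }
        )


@dataclass
class PartitionSet:
    """Repeated balanced train/test splits of the sample set."""

    partitions: list  # list of (train_ids, test_ids) tuples of lists
    seed: int

    @property
    def n_partitions(self) -> int:
        return len(self.partitions)

    def __iter__(self):
        return iter(self.partitions)

    def __getitem__(self, i):
        return self.partitions[i]


@dataclass
class PPVMatrix:
    """PPV indexed by evaluation-set size (rows) x partition (columns)."""

    values: pd.DataFrame
    method: str
    measure: str
    statistic: str
    truncated_sizes: set = field(default_factory=set)

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        finite = arr[np.isfinite(arr)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("PPV entries must lie in [0, 1]")
        sizes = np.asarray(self.values.index)
        if np.any(np.diff(sizes) <= 0):
            raise ValueError("evaluation-set sizes must be strictly increasing")

    @property
    def sizes(self) -> np.ndarray:
        return np.asarray(self.values.index)

    def row(self, size: int) -> np.ndarray:
        return self.values.loc[size].to_numpy(dtype=float)

    def mean_curve(self) -> pd.Series:
        return self.values.mean(axis=1)

    def to_long(self) -> pd.DataFrame:
        long = self.values.stack().rename("ppv").reset_index()
        long.columns = ["size", "partition", "ppv"]
        long["method"] = self.method
        long["measure"] = self.measure
        long["statistic"] = self.statistic
        return long


@dataclass
class Decomposition:
    """Result of an SVD or NMF factorisation of a CpG x sample matrix."""

    method: str  # "SVD" | "NMF"
    basis: pd.DataFrame  # CpG x k
    scores: pd.DataFrame  # k x sample
    k: int
    singular_values: np.ndarray | None = None
    objective_trace: np.ndarray | None = None


@dataclass
class ComponentAssociation:
    """Per-component phenotype R-squared plus the mean of the best two."""

    r2: np.ndarray
    best_two_mean: float


# ---------------------------------------------------------------------------
# Text I/O (tab-delimited, measure recorded in a leading metadata line)
# ---------------------------------------------------------------------------

def write_matrix_tsv(matrix: MethylationMatrix, path) -> None:
    """Write a methylation matrix as TSV with a ``# measure=...`` header line."""
    with open(path, "w") as fh:
        fh.write(f"# measure={matrix.measure}\n")
        matrix.values.to_csv(fh, sep="\t", index_label="cpg")


def read_matrix_tsv(path) -> MethylationMatrix:
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# measure="):
            measure = first.strip().split("=", 1)[1]
            values = pd.read_csv(fh, sep="\t", index_col=0)
        else:
            measure = "beta"
            fh.seek(0)
            values = pd.read_csv(fh, sep="\t", index_col=0)
    return MethylationMatrix(values, measure)


def write_phenotype_tsv(phenotype: Phenotype, path) -> None:
    frame = pd.DataFrame({"sample": phenotype.sample_ids, "value": phenotype.values.to_numpy()})
    with open(path, "w") as fh:
        fh.write(f"# kind={phenotype.kind}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_phenotype_tsv(path) -> Phenotype:
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# kind="):
            kind = first.strip().split("=", 1)[1]
        else:
            raise ValueError("phenotype TSV must start with a '# kind=' line")
        frame = pd.read_csv(fh, sep="\t")
    series = pd.Series(frame["value"].to_numpy(), index=pd.Index(frame["sample"].astype(str)))
    return Phenotype(series, kind)


def write_truth_tsv(truth: SyntheticTruth, path) -> None:
    frame = pd.DataFrame(
        {
            "cpg": truth.true_feature_ids,
            "effect": truth.effects.to_numpy(),
            "direction": truth.directions.to_numpy(),
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def write_association_tsv(assoc: pd.DataFrame, path) -> None:
    assoc.to_csv(path, sep="\t", index_label="cpg")
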