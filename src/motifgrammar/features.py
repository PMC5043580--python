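"""Peaks x motifs feature matrices (motif counts and motifs-per-kb).

The classifier input is a labeled matrix M (n peaks x p motifs) whose cells
are motif occurrences normalized per kilobase of peak, so peaks of different
lengths are comparable.  Counting and normalization are explicit, flagged
steps: raw integer counts stay raw until ``normalize_per_kb`` is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import PeakSet
from .motifs import ALPHABET, BackgroundModel, PWM, count_occurrences

POSITIVE, BACKGROUND = "positive", "background"


@dataclass
class FeatureMatrix:
    peak_ids: list[str]
    motif_ids: list[str]
    values: np.ndarray  # n_peaks x n_motifs, >= 0
    labels: list[str] | None = None  # per-peak class, or None if unlabeled
    normalized: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape != (len(self.peak_ids), len(self.motif_ids)):
            raise ValueError("feature matrix shape inconsistent with id lists")
        if np.any(v < 0):
            raise ValueError("feature values must be non-negative")
        self.values = v
        if self.labels is not None and len(self.labels) != len(self.peak_ids):
            raise ValueError("labels must be given for every row")

    @property
    def n_peaks(self) -> int:
        return len(self.peak_ids)

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.peak_ids, columns=self.motif_ids)
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        return df

    def subset_rows(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(
            [self.peak_ids[i] for i in idx],
            list(self.motif_ids),
            self.values[idx],
            [self.labels[i] for i in idx] if self.labels is not None else None,
            self.normalized,
        )

    def to_tsv(self, path: str | Path) -> None:
        df = self.frame()
        df.index.name = "peak_id"
        with open(path, "w") as fh:
            fh.write(f"# normalized={str(self.normalized).lower()}\n")
            df.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        with open(path) as fh:
            first = fh.readline()
            normalized = "normalized=true" in first
            df = pd.read_csv(fh, sep="\t", index_col=0)
        labels = None
        if "label" in df.columns:
            labels = df.pop("label").tolist()
        return cls(
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            df.to_numpy(dtype=float),
            labels,
            normalized,
        )


@dataclass(frozen=True)
class DataSplit:
    train_indices: np.ndarray
    test_indices: np.ndarray
    fraction: float
    seed: int


def background_from_sequences(
    sequences: Mapping[str, str] | Sequence[str], pseudocount: float = 1.0
) -> BackgroundModel:
    """Zero-order background from pooled base counts (pseudocount 1 per base)."""
    seqs = sequences.values() if isinstance(sequences, Mapping) else sequences
    counts = np.zeros(4)
    for s in seqs:
        u = s.upper()
        for i, b in enumerate(ALPHABET):
            counts[i] += u.count(b)
    if counts.sum() == 0:
        raise ValueError("no ACGT bases in input sequences")
    return BackgroundModel.from_counts(counts, pseudocount)


def count_matrix(
    peaks: PeakSet,
    sequences: Mapping[str, str],
    pwms: Sequence[PWM],
    background: BackgroundModel,
    threshold: float = 6.0,
) -> FeatureMatrix:
    """Raw motif-hit counts (both strands) for every peak and PWM."""
    ids = peaks.ids()
    missing = [pid for pid in ids if pid not in sequences]
    if missing:
        raise KeyError(f"no sequence for peak(s): {', '.join(missing[:5])}")
    seqs = [sequences[pid] for pid in ids]
    counts = count_occurrences(pwms, seqs, background, threshold)
    return FeatureMatrix(ids, [p.id for p in pwms], counts.astype(float))


def normalize_per_kb(matrix: FeatureMatrix, lengths: Sequence[int]) -> FeatureMatrix:
    """Convert raw counts to motifs per kilobase of peak."""
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    lens = np.asarray(lengths, dtype=float)
    if lens.shape != (matrix.n_peaks,):
        raise ValueError("one length per peak required")
    if np.any(lens <= 0):
        raise ValueError("peak lengths must be positive")
    return replace(
        matrix, values=matrix.values / (lens[:, None] / 1000.0), normalized=True
    )


def stack_labeled(positive: FeatureMatrix, background: FeatureMatrix) -> FeatureMatrix:
    """Concatenate positive and background rows with class labels."""
    if positive.motif_ids != background.motif_ids:
        raise ValueError("motif id columns differ between positive and background")
    if background.n_peaks == 0 or positive.n_peaks == 0:
        raise ValueError("both classes must be non-empty")
    if positive.normalized != background.normalized:
        raise ValueError("cannot stack a normalized with an unnormalized matrix")
    return FeatureMatrix(
        positive.peak_ids + background.peak_ids,
        list(positive.motif_ids),
        np.vstack([positive.values, background.values]),
        [POSITIVE] * positive.n_peaks + [BACKGROUND] * background.n_peaks,
        positive.normalized,
    )


def train_test_split(
    matrix: FeatureMatrix, fraction: float = 0.75, seed: int = 0
) -> DataSplit:
    """Stratified split: the fraction is applied independently within each class."""
    if matrix.labels is None:
        raise ValueError("matrix must be labeled")
    if not 0.0 < fraction < 1.0:
        raise ValueError("train fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = np.asarray(matrix.labels)
    train, test = [], []
    for cls in sorted(set(matrix.labels)):
        idx = np.nonzero(labels == cls)[0]
        if idx.size < 4:
            raise ValueError(f"class {cls!r} has fewer than 4 rows")
        perm = rng.permutation(idx)
        k = int(round(fraction * idx.size))
        k = min(max(k, 1), idx.size - 1)
        train.extend(perm[:k])
        test.extend(perm[k:])
    return DataSplit(
        np.array(sorted(train)), np.array(sorted(test)), fraction, seed
    )


@dataclass
class Featurizer:
    """Reusable featurization context: PWM library, background and threshold.

    Applying a trained model to new peaks must use the same motif library,
    scan threshold, background model and per-kb normalization as training;
    this object carries that state.
    """

    pwms: Sequence[PWM]
    background: BackgroundModel
    threshold: float = 6.0
    chromosomes: Mapping[str, str] | None = None  # in-memory genome override
    genome: str | Path | None = None

    def peak_sequences(self, peaks: PeakSet) -> dict[str, str]:
        if self.chromosomes is not None:
            out = {}
            for iv in peaks:
                chrom = self.chromosomes.get(iv.chrom)
                if chrom is None or iv.end > len(chrom):
                    raise KeyError(f"peak {iv.id}: outside the in-memory genome")
                out[iv.id] = chrom[iv.start : iv.end].upper()
            return out
        if self.genome is None:
            raise ValueError("featurizer needs either chromosomes or a genome FASTA")
        from .intervals import extract_sequences

        return extract_sequences(peaks, self.genome)

    def counts(self, peaks: PeakSet) -> FeatureMatrix:
        return count_matrix(
            peaks, self.peak_sequences(peaks), self.pwms, self.background, self.threshold
        )

    def features(self, peaks: PeakSet) -> FeatureMatrix:
        return normalize_per_kb(self.counts(peaks), peaks.lengths())
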