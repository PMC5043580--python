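"""Binary motif co-occurrence within positive peaks.

A motif is "present" in a peak when its raw hit count reaches a minimum
(default 1).  The co-occurrence matrix reports, for each motif pair, the
fraction of all peaks containing both; its diagonal is each motif's
prevalence.  The anchor-exclusive fraction asks how often a motif occurs in
peaks that lack the anchor motif entirely - the signature of indirect
(tethered) binding - computed as freq(m) - freq(m AND anchor) over all
peaks (the frequency-subtraction form); a per-motif-conditioned variant
(|m AND not anchor| / |m|) is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .models import FittedModel


@dataclass
class CooccurrenceMatrix:
    motif_ids: list[str]
    matrix: np.ndarray  # symmetric, proportions in [0, 1]
    n_peaks: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.motif_ids, columns=self.motif_ids)

    def to_tsv(self, path: str | Path) -> None:
        df = self.frame()
        df.index.name = "motif_id"
        df.to_csv(path, sep="\t")


@dataclass
class AnchorExclusiveReport:
    anchor: str
    fractions: dict[str, float]  # per motif, anchor's own entry is 0
    denominator: str  # "all_peaks" or "motif_peaks"
    n_peaks: int

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"motif_id": list(self.fractions), "exclusive_fraction": list(self.fractions.values())}
        )
        df.to_csv(path, sep="\t", index=False)


def binarize(matrix: FeatureMatrix, min_count: int = 1) -> FeatureMatrix:
    """Presence/absence table from raw counts (>= min_count per peak)."""
    if matrix.normalized:
        raise ValueError("binarization must act on raw counts, not per-kb values")
    return FeatureMatrix(
        list(matrix.peak_ids),
        list(matrix.motif_ids),
        (matrix.values >= min_count).astype(float),
        list(matrix.labels) if matrix.labels is not None else None,
        normalized=False,
    )


def _presence_array(presence: FeatureMatrix, motif_ids: Sequence[str] | None):
    ids = list(motif_ids) if motif_ids is not None else list(presence.motif_ids)
    missing = [m for m in ids if m not in presence.motif_ids]
    if missing:
        raise KeyError(f"motifs not in the presence table: {missing[:5]}")
    cols = [presence.motif_ids.index(m) for m in ids]
    B = presence.values[:, cols]
    if not np.isin(B, (0.0, 1.0)).all():
        raise ValueError("presence table must be binary; call binarize() first")
    return ids, B


def cooccurrence_matrix(
    presence: FeatureMatrix, motif_ids: Sequence[str] | None = None
) -> CooccurrenceMatrix:
    """Pairwise fraction of all peaks containing both motifs."""
    ids, B = _presence_array(presence, motif_ids)
    n = B.shape[0]
    mat = (B.T @ B) / n if n else np.zeros((len(ids), len(ids)))
    return CooccurrenceMatrix(ids, mat, n)


def anchor_exclusive_fraction(
    presence: FeatureMatrix, anchor: str, denominator: str = "all_peaks"
) -> AnchorExclusiveReport:
    """Per motif: how often it occurs in peaks lacking the anchor motif.

    ``all_peaks`` (default): |peaks with m and without anchor| / n_peaks,
    i.e. freq(m) minus freq(m and anchor).  ``motif_peaks``: the same count
    divided by |peaks with m|.  The anchor's own entry is 0 by construction.
    """
    ids, B = _presence_array(presence, None)
    if anchor not in ids:
        raise KeyError(f"anchor {anchor!r} not in the presence table")
    if denominator not in ("all_peaks", "motif_peaks"):
        raise ValueError("denominator must be 'all_peaks' or 'motif_peaks'")
    n = B.shape[0]
    a = B[:, ids.index(anchor)]
    fractions: dict[str, float] = {}
    for j, m in enumerate(ids):
        both = float(np.sum((B[:, j] == 1) & (a == 0)))
        if denominator == "all_peaks":
            fractions[m] = both / n if n else 0.0
        else:
            nm = float(B[:, j].sum())
            fractions[m] = both / nm if nm else 0.0
    fractions[anchor] = 0.0
    return AnchorExclusiveReport(anchor, fractions, denominator, n)


def rank_candidates(
    model: FittedModel,
    exclusive: AnchorExclusiveReport,
    known_ppis: Sequence[str] = (),
) -> pd.DataFrame:
    """Candidate cofactors: active non-anchor motifs ranked by |coefficient|.

    Each row carries the model weight, the anchor-exclusive fraction (how
    often the motif appears without the anchor, suggesting tethering) and a
    known/novel interaction flag.
    """
    known = set(known_ppis)
    rows = []
    for m, c in model.active_features.items():
        if m == exclusive.anchor:
            continue
        rows.append(
            {
                "motif_id": m,
                "coefficient": c,
                "exclusive_fraction": exclusive.fractions.get(m, float("nan")),
                "known_ppi": m in known,
            }
        )
    df = pd.DataFrame(rows, columns=["motif_id", "coefficient", "exclusive_fraction", "known_ppi"])
    if len(df):
        df = df.reindex(df.coefficient.abs().sort_values(ascending=False).index)
        df = df.reset_index(drop=True)
    return df
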