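"""Position weight matrices and log-likelihood motif scanning.

A :class:`PWM` is a position x base probability matrix over the DNA alphabet
(A, C, G, T).  Windows of a sequence are scored as the sum of per-position
log2 likelihood ratios against a zero-order :class:`BackgroundModel` ("bits"),
and a motif instance is recorded wherever the score on either strand reaches
a threshold (default 6 bits, the conventional CLOVER-style cutoff).

Readers are provided for the three common motif-library dialects (MEME
minimal, JASPAR PFM, TRANSFAC); parsing of the raw records is delegated to
``Bio.motifs`` and the resulting count matrices are pseudocounted and
normalized here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

ALPHABET = "ACGT"
#: integer codes: A=0 C=1 G=2 T=3, anything else (N, ambiguity codes) = 4
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
#: column permutation sending a base to its complement
_COMPLEMENT = np.array([3, 2, 1, 0])

NEG_INF = float("-inf")


class MotifParseError(ValueError):
    """A motif library record could not be parsed or validated."""


@dataclass(frozen=True)
class BackgroundModel:
    """Zero-order (single-base) background distribution over A, C, G, T."""

    freqs: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (4,):
            raise ValueError("background must have exactly 4 frequencies")
        if not np.all(f > 0):
            raise ValueError("background frequencies must be strictly positive")
        if abs(float(f.sum()) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1 (within 1e-9)")
        object.__setattr__(self, "freqs", f)

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls(np.full(4, 0.25))

    @classmethod
    def from_counts(cls, counts: Sequence[float], pseudocount: float = 1.0) -> "BackgroundModel":
        c = np.asarray(counts, dtype=float) + pseudocount
        return cls(c / c.sum())


@dataclass
class PWM:
    """Position probability matrix: ``probs[i, b]`` with rows summing to 1."""

    id: str
    probs: np.ndarray
    name: str = ""
    source: str = "synthetic"

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4 or p.shape[0] < 1:
            raise ValueError(f"PWM {self.id!r}: probs must be a width x 4 matrix, width >= 1")
        if np.any(p < 0):
            raise ValueError(f"PWM {self.id!r}: negative probabilities")
        if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError(f"PWM {self.id!r}: rows must sum to 1 within 1e-6")
        self.probs = p
        if not self.name:
            self.name = self.id

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    position: int  # 0-based forward-strand offset of the window start
    strand: str  # "+" or "-"
    score: float  # bits


def reverse_complement(pwm: PWM) -> PWM:
    """Reverse the position order and swap A<->T, C<->G.  An involution."""
    return replace(pwm, probs=pwm.probs[::-1, _COMPLEMENT])


def encode(sequence: str) -> np.ndarray:
    """Map a DNA string to integer codes (non-ACGT bases -> 4)."""
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def log_odds(pwm: PWM, background: BackgroundModel, pseudocount: float = 0.0) -> np.ndarray:
    """Per-position log2 likelihood-ratio matrix, width x 5.

    Column 4 (any non-ACGT base) is -inf so a window containing an N can
    never reach a finite threshold.  ``pseudocount`` is added to every
    probability cell and rows renormalized before taking the ratio.
    """
    p = pwm.probs
    if pseudocount:
        p = p + pseudocount
        p = p / p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore"):
        lo = np.log2(p / background.freqs)
    return np.hstack([lo, np.full((pwm.width, 1), NEG_INF)])


def log_likelihood_score(
    pwm: PWM,
    window: str,
    background: BackgroundModel,
    pseudocount: float = 0.0,
) -> float:
    """Score one window of length ``pwm.width`` in bits.

    Any N in the window yields -inf.
    """
    if len(window) != pwm.width:
        raise ValueError(f"window length {len(window)} != PWM width {pwm.width}")
    lo = log_odds(pwm, background, pseudocount)
    codes = encode(window)
    return float(lo[np.arange(pwm.width), codes].sum())


def _window_scores(lo: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Scores of every window of ``codes`` under the width x 5 log-odds matrix."""
    w = lo.shape[0]
    n = codes.size - w + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for i in range(w):
        scores += lo[i, codes[i : i + n]]
    return scores


def _revcomp_log_odds(lo: np.ndarray) -> np.ndarray:
    """Reverse-complement a width x 5 log-odds matrix (N column preserved)."""
    out = lo[::-1].copy()
    out[:, :4] = out[:, _COMPLEMENT]
    return out


def scan_sequence(
    pwm: PWM,
    sequence: str,
    background: BackgroundModel,
    threshold: float = 6.0,
    pseudocount: float = 0.0,
    merge_overlaps: bool = False,
) -> list[MotifHit]:
    """All windows on both strands with finite score >= ``threshold``.

    Positions are forward-strand window starts for both strands.  Overlapping
    hits are all kept by default; ``merge_overlaps`` applies a greedy
    best-score-first suppression of overlapping hits.
    """
    codes = encode(sequence)
    lo = log_odds(pwm, background, pseudocount)
    hits: list[MotifHit] = []
    for strand, mat in (("+", lo), ("-", _revcomp_log_odds(lo))):
        scores = _window_scores(mat, codes)
        for pos in np.nonzero(scores >= threshold)[0]:
            hits.append(MotifHit(pwm.id, int(pos), strand, float(scores[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    if merge_overlaps:
        kept: list[MotifHit] = []
        for h in sorted(hits, key=lambda h: (-h.score, h.position, h.strand)):
            if all(
                h.position + pwm.width <= k.position or k.position + pwm.width <= h.position
                for k in kept
            ):
                kept.append(h)
        hits = sorted(kept, key=lambda h: (h.position, h.strand))
    return hits


def count_occurrences(
    pwms: Sequence[PWM],
    sequences: Sequence[str],
    background: BackgroundModel,
    threshold: float = 6.0,
    pseudocount: float = 0.0,
) -> np.ndarray:
    """Hit counts (both strands) for every (sequence, PWM) pair.

    Equivalent to ``len(scan_sequence(...))`` per cell but vectorized across
    sequences: all sequences are concatenated with N spacers (which score
    -inf, so no window crossing a boundary can ever count).
    """
    n_seq, n_pwm = len(sequences), len(pwms)
    counts = np.zeros((n_seq, n_pwm), dtype=np.int64)
    if n_seq == 0 or n_pwm == 0:
        return counts
    max_w = max(p.width for p in pwms)
    sep = np.full(max_w, 4, dtype=np.int8)
    parts, offsets = [], []
    pos = 0
    for s in sequences:
        offsets.append(pos)
        c = encode(s)
        parts.append(c)
        parts.append(sep)
        pos += c.size + max_w
    big = np.concatenate(parts)
    bounds = np.array(offsets + [big.size])
    for j, pwm in enumerate(pwms):
        lo = log_odds(pwm, background, pseudocount)
        above = (_window_scores(lo, big) >= threshold).astype(np.int64)
        above = np.concatenate([above, np.zeros(big.size - above.size, dtype=np.int64)])
        cum = np.concatenate([[0], np.cumsum(above)])
        rc = _revcomp_log_odds(lo)
        above_rc = (_window_scores(rc, big) >= threshold).astype(np.int64)
        above_rc = np.concatenate([above_rc, np.zeros(big.size - above_rc.size, dtype=np.int64)])
        cum_rc = np.concatenate([[0], np.cumsum(above_rc)])
        counts[:, j] = (cum[bounds[1:]] - cum[bounds[:-1]]) + (
            cum_rc[bounds[1:]] - cum_rc[bounds[:-1]]
        )
    return counts


def information_content(pwm: PWM, background: BackgroundModel) -> float:
    """Total relative entropy of the PWM against the background, in bits."""
    p = pwm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / background.freqs), 0.0)
    return float(terms.sum())


def _column_correlation(u: np.ndarray, v: np.ndarray) -> float:
    su, sv = u.std(), v.std()
    if su < 1e-12 and sv < 1e-12:
        return 1.0 if np.allclose(u, v) else 0.0
    if su < 1e-12 or sv < 1e-12:
        return 0.0
    return float(((u - u.mean()) * (v - v.mean())).mean() / (su * sv))


def pwm_similarity(a: PWM, b: PWM, min_overlap: int = 4) -> float:
    """Ungapped alignment similarity in [-1, 1].

    Maximum over all relative offsets, and over ``b`` versus its reverse
    complement, of the mean column-wise Pearson correlation across the
    overlapping columns (at least ``min_overlap`` columns, or the full
    shorter width if that is smaller).  Symmetric in its arguments.
    """
    wa, wb = a.width, b.width
    minov = min(min_overlap, wa, wb)
    best = -1.0
    for bp in (b.probs, reverse_complement(b).probs):
        for shift in range(-(wb - minov), wa - minov + 1):
            lo = max(0, shift)
            hi = min(wa, wb + shift)
            if hi - lo < minov:
                continue
            cols = [
                _column_correlation(a.probs[i], bp[i - shift]) for i in range(lo, hi)
            ]
            best = max(best, float(np.mean(cols)))
    return float(np.clip(best, -1.0, 1.0))


# ---------------------------------------------------------------------------
# library I/O


_FORMAT_BY_SUFFIX = {
    ".meme": "meme",
    ".txt": "meme",
    ".jaspar": "jaspar_pfm",
    ".pfm": "jaspar_pfm",
    ".transfac": "transfac",
    ".dat": "transfac",
}
_SOURCE_TAG = {"meme": "meme", "jaspar_pfm": "jaspar", "transfac": "transfac"}


def _counts_to_pwm(mid, name, counts, source, pseudocount):
    counts = np.asarray(counts, dtype=float)
    if not np.all(np.isfinite(counts)) or np.any(counts < 0):
        raise MotifParseError(f"motif {mid!r}: negative or non-numeric counts")
    rowsum = counts.sum(axis=1)
    if pseudocount == 0 and np.any(rowsum == 0):
        raise MotifParseError(
            f"motif {mid!r}: position with all-zero counts and zero pseudocount"
        )
    probs = (counts + pseudocount) / (rowsum + 4 * pseudocount)[:, None]
    return PWM(id=str(mid), name=str(name or mid), probs=probs, source=source)


def read_pwm_library(
    path: str | Path,
    format: str | None = None,
    pseudocount: float = 1e-4,
) -> list[PWM]:
    """Read a motif library in MEME-minimal, JASPAR PFM or TRANSFAC format.

    The dialect is auto-detected from the file extension unless ``format``
    (one of ``meme``, ``jaspar_pfm``, ``transfac``) is given.  Count matrices
    are normalized position-wise to probabilities after adding
    ``pseudocount`` to every cell.  Duplicate ids are an error.
    """
    import Bio.motifs

    path = Path(path)
    fmt = format or _FORMAT_BY_SUFFIX.get(path.suffix.lower())
    if fmt not in _SOURCE_TAG:
        raise MotifParseError(
            f"cannot infer motif format from {path.name!r}; pass format explicitly"
        )
    if fmt == "meme":
        raw = _parse_meme_minimal(path)
    else:
        bio_fmt = {"jaspar_pfm": "jaspar", "transfac": "transfac"}[fmt]
        try:
            with open(path) as fh:
                records = list(Bio.motifs.parse(fh, bio_fmt))
        except Exception as exc:  # malformed record inside Bio.motifs
            raise MotifParseError(f"failed to parse {path.name} as {fmt}: {exc}") from exc
        raw = []
        for rec in records:
            if bio_fmt == "jaspar":
                mid = rec.matrix_id or rec.name
                name = rec.name
            else:
                mid = rec.get("ID") or rec.get("AC") or rec.name
                name = rec.get("NA") or mid
            raw.append((mid, name, np.array([rec.counts[b] for b in ALPHABET]).T))

    pwms: list[PWM] = []
    seen: set[str] = set()
    for mid, name, counts in raw:
        pwm = _counts_to_pwm(mid, name, counts, _SOURCE_TAG[fmt], pseudocount)
        if pwm.id in seen:
            raise MotifParseError(f"duplicate motif id {pwm.id!r} in {path.name}")
        seen.add(pwm.id)
        pwms.append(pwm)
    return pwms


def _parse_meme_minimal(path: Path) -> list[tuple[str, str, np.ndarray]]:
    """MEME minimal motif format: MOTIF blocks with letter-probability rows."""
    raw: list[tuple[str, str, np.ndarray]] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise MotifParseError(f"{path.name}: MOTIF line without identifier")
            mid = parts[1]
            name = parts[2] if len(parts) > 2 else mid
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                if lines[i].strip().startswith("MOTIF"):
                    raise MotifParseError(f"motif {mid!r}: missing probability matrix")
                i += 1
            if i >= len(lines):
                raise MotifParseError(f"motif {mid!r}: missing probability matrix")
            header = lines[i]
            width = None
            toks = header.replace("=", " = ").split()
            for j, t in enumerate(toks):
                if t == "w" and j + 2 < len(toks) and toks[j + 1] == "=":
                    width = int(toks[j + 2])
            if width is None:
                raise MotifParseError(f"motif {mid!r}: matrix header lacks w=")
            rows = []
            for k in range(width):
                i += 1
                if i >= len(lines):
                    raise MotifParseError(f"motif {mid!r}: truncated matrix")
                vals = lines[i].split()
                if len(vals) != 4:
                    raise MotifParseError(
                        f"motif {mid!r}: matrix row with {len(vals)} columns"
                    )
                try:
                    rows.append([float(v) for v in vals])
                except ValueError as exc:
                    raise MotifParseError(f"motif {mid!r}: non-numeric matrix entry") from exc
            raw.append((mid, name, np.array(rows)))
        i += 1
    if not raw:
        raise MotifParseError(f"{path.name}: no MOTIF records found")
    return raw


def write_meme(pwms: Iterable[PWM], path: str | Path, background: BackgroundModel | None = None) -> None:
    """Write PWMs as a MEME-minimal motif file."""
    bg = background.freqs if background is not None else np.full(4, 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip(ALPHABET, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.id} {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} nsites= 20 E= 0\n"
            )
            for row in pwm.probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")
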