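"""Synthetic genomes, replicate peak sets and planted motif grammar.

The generator emulates the statistical structure that the analysis assumes:

* a zero-order genome at a configurable GC content, with "allowed" promoter
  regions tiling it (backgrounds are constrained to promoter space, as on a
  promoter tiling array);
* two replicate positive peak sets that share a target fraction of
  coordinates (about 55% in typical replicate DNA-binding experiments) and,
  crucially, share the same motif grammar in their non-overlapping peaks;
* an anchor motif planted in most positives, a set of cofactor motifs
  planted at lower rates (with a small leak rate into the background), and
  decoy motifs that are never planted;
* an indirect-binding subset of positives that carries at least one
  cofactor motif but never the anchor - peaks bound by tethering rather
  than by the anchor's own element;
* a ground-truth table of every planted instance, so scanner, classifier
  and co-occurrence stages can all be validated.

Replicate 2 reuses replicate-1 coordinates with probability proportional to
(1 + planted motif count) ** reproducibility_bias: grammar-dense (strongly
bound) peaks reproduce preferentially, which is what makes shared peaks
better predicted than replicate-unique peaks downstream.

The default anchor PWM is deliberately short and soft (width 8, dominant
base probability 0.88), mimicking the low information content of real
homeodomain elements: it accrues chance matches throughout the genome and
is therefore an informative but not dominant classifier feature.  Cofactor
and decoy PWMs are longer and sharper, so planted instances are recovered
nearly perfectly at the default 6-bit scan threshold while chance matches
stay rare.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import background_from_sequences, Featurizer
from .intervals import GenomicInterval, PeakSet, place_random_intervals, write_bed
from .motifs import ALPHABET, BackgroundModel, PWM, write_meme

_BASES = np.array(list(ALPHABET))


def random_pwm(
    rng: np.random.Generator,
    width: int,
    sharpness: float,
    id: str,
    source: str = "synthetic",
) -> PWM:
    """PWM with a random consensus; each position puts ``sharpness`` mass on
    the consensus base and the remainder spread over the other three."""
    probs = np.full((width, 4), (1.0 - sharpness) / 3.0)
    consensus = rng.integers(0, 4, size=width)
    probs[np.arange(width), consensus] = sharpness
    return PWM(id=id, probs=probs, source=source)


def sample_instance(pwm: PWM, rng: np.random.Generator) -> str:
    """One realization of the motif, sampled column-wise from the PWM."""
    cum = pwm.probs.cumsum(axis=1)
    idx = (rng.random(pwm.width)[:, None] > cum).sum(axis=1)
    return "".join(_BASES[idx])


_RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def plant_motif(
    sequence: str,
    pwm: PWM,
    position: int,
    strand: str,
    rng: np.random.Generator,
) -> str:
    """Replace the width-long window at ``position`` with a sampled instance
    (reverse-complemented for the minus strand); the rest is unchanged."""
    if position < 0 or position + pwm.width > len(sequence):
        raise ValueError(
            f"planting position {position} does not fit motif width {pwm.width} "
            f"in a sequence of length {len(sequence)}"
        )
    inst = sample_instance(pwm, rng)
    if strand == "-":
        inst = revcomp(inst)
    return sequence[:position] + inst + sequence[position + pwm.width :]


@dataclass
class SyntheticConfig:
    """Study conditions for one simulated pair of replicate experiments."""

    n_pos: int = 500
    n_bg: int = 500
    length_mean: float = 500.0
    length_sd: float = 120.0
    length_min: int = 100
    length_max: int = 1200
    gc_content: float = 0.42
    anchor: PWM | None = None  # default: width 7, sharpness 0.85
    anchor_prob: float = 0.6
    cofactors: list[tuple[PWM, float, float]] = field(default_factory=list)
    # (PWM, planting probability in positives, leak probability in background)
    decoys: list[PWM] = field(default_factory=list)
    indirect_fraction: float = 0.15
    replicate_overlap: float = 0.55
    reproducibility_bias: float = 1.0
    genome_length: int | None = None
    region_length: int = 5000
    region_gap: int = 500
    seed: int = 0

    def validate(self) -> None:
        for p, what in [
            (self.anchor_prob, "anchor_prob"),
            (self.indirect_fraction, "indirect_fraction"),
            (self.replicate_overlap, "replicate_overlap"),
            (self.gc_content, "gc_content"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{what} must be in [0, 1], got {p}")
        for _, p, leak in self.cofactors:
            if not (0.0 <= p <= 1.0 and 0.0 <= leak <= 1.0):
                raise ValueError("cofactor probabilities must be in [0, 1]")
        if self.indirect_fraction == 1.0 and self.anchor_prob == 1.0:
            raise ValueError(
                "inconsistent config: every positive indirect (no anchor) but "
                "anchor planting probability 1"
            )
        if not self.cofactors and self.indirect_fraction > 0:
            raise ValueError("indirect positives need at least one cofactor")
        maxw = max(p.width for p in self.all_pwms())
        if self.length_min < 2 * maxw:
            raise ValueError("minimum peak length must be >= 2x the widest motif")

    def all_pwms(self) -> list[PWM]:
        pwms = []
        if self.anchor is not None:
            pwms.append(self.anchor)
        pwms.extend(p for p, _, _ in self.cofactors)
        pwms.extend(self.decoys)
        return pwms

    def scalars(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "n_pos n_bg length_mean length_sd length_min length_max gc_content "
                "anchor_prob indirect_fraction replicate_overlap reproducibility_bias "
                "genome_length region_length region_gap seed"
            ).split()
        }


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The default strong-signal study conditions, with its motif set.

    500 positives per replicate and 500 backgrounds; anchor planted in 60%
    of direct positives; 4 cofactors at 40% (leaking into 5% of
    backgrounds); 50 decoys never planted; 15% indirect positives; 55%
    replicate coordinate overlap; GC 0.42.
    """
    rng = np.random.default_rng(seed)
    anchor = random_pwm(rng, 8, 0.88, "ANCHOR")
    cof_prob = overrides.pop("cofactor_prob", 0.4)
    cof_leak = overrides.pop("cofactor_leak", 0.05)
    n_cof = overrides.pop("n_cofactors", 4)
    n_dec = overrides.pop("n_decoys", 50)
    cofactors = [
        (random_pwm(rng, 18, 0.95, f"COF{i + 1}"), cof_prob, cof_leak)
        for i in range(n_cof)
    ]
    decoys = [
        random_pwm(rng, int(rng.integers(8, 13)), 0.85, f"DECOY{i + 1:02d}")
        for i in range(n_dec)
    ]
    cfg = SyntheticConfig(
        anchor=anchor, cofactors=cofactors, decoys=decoys, seed=seed, **overrides
    )
    cfg.validate()
    return cfg


@dataclass
class SyntheticTruth:
    """Ground truth: every planted instance and every peak's provenance."""

    plantings: pd.DataFrame  # peak_id, set, motif_id, offset, strand
    peaks: pd.DataFrame  # peak_id, set, cls, shared, chrom, start, end

    def peaks_lacking(self, motif_id: str, which: str) -> list[str]:
        sub = self.peaks[self.peaks["set"] == which]
        have = set(
            self.plantings[
                (self.plantings["set"] == which)
                & (self.plantings["motif_id"] == motif_id)
            ]["peak_id"]
        )
        return [p for p in sub["peak_id"] if p not in have]


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    chromosomes: dict[str, str]
    allowed: PeakSet
    rep1: PeakSet
    rep2: PeakSet
    background: PeakSet
    truth: SyntheticTruth

    def sequences(self, peaks: PeakSet) -> dict[str, str]:
        out = {}
        for iv in peaks:
            out[iv.id] = self.chromosomes[iv.chrom][iv.start : iv.end]
        return out

    def featurizer(
        self, threshold: float = 6.0, background: BackgroundModel | None = None
    ) -> Featurizer:
        if background is None:
            pooled = {**self.sequences(self.rep1), **self.sequences(self.background)}
            background = background_from_sequences(pooled)
        return Featurizer(
            pwms=self.config.all_pwms(),
            background=background,
            threshold=threshold,
            chromosomes=self.chromosomes,
        )


def simulate_genome(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, np.ndarray], PeakSet]:
    """IID genome at the configured GC plus tiled allowed regions.

    Returns the genome as mutable per-chromosome character arrays (planting
    happens in place) and the allowed-region peak set; gaps between regions
    constrain background placement.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    G = config.genome_length or max(
        1_000_000, int(4 * (2 * config.n_pos + config.n_bg) * config.length_mean)
    )
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=G, p=p)
    genome = {"chr1": _BASES[codes].copy()}
    allowed = []
    pos = 0
    i = 0
    step = config.region_length + config.region_gap
    while pos + config.region_length <= G:
        allowed.append(
            GenomicInterval("chr1", pos, pos + config.region_length, f"region_{i:05d}")
        )
        pos += step
        i += 1
    return genome, PeakSet("allowed", allowed)


def _sample_lengths(config: SyntheticConfig, n: int, rng) -> np.ndarray:
    out = np.empty(n, dtype=int)
    filled = 0
    while filled < n:
        draw = rng.normal(config.length_mean, config.length_sd, size=2 * (n - filled))
        draw = draw[(draw >= config.length_min) & (draw <= config.length_max)]
        take = min(draw.size, n - filled)
        out[filled : filled + take] = draw[:take].astype(int)
        filled += take
    return out


def _plant_into(genome_arr, interval, pwm, strand, rng, taken):
    """Plant one instance at a collision-free uniform offset; returns offset."""
    w = pwm.width
    for _ in range(100):
        off = int(rng.integers(0, interval.length - w + 1))
        if all(off + w <= s or e <= off for s, e in taken):
            break
    else:
        raise RuntimeError(
            f"no collision-free planting position in peak {interval.id}"
        )
    inst = sample_instance(pwm, rng)
    if strand == "-":
        inst = revcomp(inst)
    genome_arr[interval.start + off : interval.start + off + w] = list(inst)
    taken.append((off, off + w))
    return off


def _plant_peak(genome_arr, interval, cls, config, rng, records, set_name):
    """Plant anchor/cofactors into one positive peak according to its class."""
    taken: list[tuple[int, int]] = []
    planted_cof = []
    for pwm, prob, _ in config.cofactors:
        if rng.random() < prob:
            planted_cof.append(pwm)
    if cls == "indirect" and not planted_cof:
        planted_cof.append(config.cofactors[rng.integers(len(config.cofactors))][0])
    plant_anchor = cls == "direct" and rng.random() < config.anchor_prob
    for pwm in ([config.anchor] if plant_anchor else []) + planted_cof:
        strand = "+" if rng.random() < 0.5 else "-"
        off = _plant_into(genome_arr, interval, pwm, strand, rng, taken)
        records.append(
            {
                "peak_id": interval.id,
                "set": set_name,
                "motif_id": pwm.id,
                "offset": off,
                "strand": strand,
            }
        )


def simulate_peaks(config: SyntheticConfig) -> SyntheticDataset:
    """Full simulation: genome, replicate peak sets, background and truth.

    Deterministic given ``config.seed``.  Replicate 2 reuses a
    ``replicate_overlap`` fraction of replicate-1 coordinates (jittered by up
    to 10% of peak length, staying inside the allowed region) and draws the
    rest fresh from the same grammar; the background receives cofactors only
    at their leak probabilities and never the anchor or decoys.
    """
    config.validate()
    if config.anchor is None:
        raise ValueError("config needs an anchor PWM (see default_config)")
    rng = np.random.default_rng(config.seed)
    genome, allowed = simulate_genome(config, rng)
    arr = genome["chr1"]

    # --- replicate 1 ----------------------------------------------------
    lengths1 = _sample_lengths(config, config.n_pos, rng)
    rep1_iv = place_random_intervals(lengths1, allowed, rng, name_prefix="rep1")
    n_ind = math.ceil(config.indirect_fraction * config.n_pos)
    ind_idx = set(rng.choice(config.n_pos, size=n_ind, replace=False).tolist())
    cls1 = ["indirect" if i in ind_idx else "direct" for i in range(config.n_pos)]

    records: list[dict] = []
    peak_rows: list[dict] = []
    for iv, cls in zip(rep1_iv, cls1):
        _plant_peak(arr, iv, cls, config, rng, records, "rep1")

    planted_per_peak = (
        pd.DataFrame(records).groupby("peak_id").size() if records else pd.Series(dtype=int)
    )
    k_planted = np.array([planted_per_peak.get(iv.id, 0) for iv in rep1_iv], dtype=float)

    # --- replicate 2: shared coordinates, strength-biased ----------------
    n_shared = int(round(config.replicate_overlap * config.n_pos))
    w = (1.0 + k_planted) ** config.reproducibility_bias
    shared_idx = rng.choice(config.n_pos, size=n_shared, replace=False, p=w / w.sum())
    shared_set = set(shared_idx.tolist())

    rep2_iv: list[GenomicInterval] = []
    cls2: list[str] = []
    rep1_by_idx = list(rep1_iv)
    rec1 = pd.DataFrame(records) if records else pd.DataFrame(
        columns=["peak_id", "set", "motif_id", "offset", "strand"]
    )
    counter = 0
    inherited_indirect = 0
    for i in sorted(shared_set):
        src = rep1_by_idx[i]
        L = src.length
        jit = int(rng.integers(-(L // 10), L // 10 + 1))
        # keep the jittered peak inside the allowed region that holds it
        region_idx = src.start // (config.region_length + config.region_gap)
        region = allowed.intervals[region_idx]
        start = min(max(src.start + jit, region.start), region.end - L)
        iv = GenomicInterval(src.chrom, start, start + L, f"rep2_{counter:05d}")
        counter += 1
        rep2_iv.append(iv)
        cls2.append(cls1[i])
        if cls1[i] == "indirect":
            inherited_indirect += 1
        # inherit the plantings that still fit inside the jittered window
        for _, r in rec1[rec1["peak_id"] == src.id].iterrows():
            gpos = src.start + r["offset"]
            w_m = next(p.width for p in config.all_pwms() if p.id == r["motif_id"])
            off2 = gpos - iv.start
            if 0 <= off2 and off2 + w_m <= iv.length:
                records.append(
                    {
                        "peak_id": iv.id,
                        "set": "rep2",
                        "motif_id": r["motif_id"],
                        "offset": int(off2),
                        "strand": r["strand"],
                    }
                )

    n_fresh = config.n_pos - n_shared
    lengths2 = _sample_lengths(config, n_fresh, rng)
    fresh_iv = place_random_intervals(
        lengths2,
        allowed,
        rng,
        exclude=list(rep1_iv) + rep2_iv,
        name_prefix="rep2f",
    )
    fresh_iv = [
        GenomicInterval(iv.chrom, iv.start, iv.end, f"rep2_{counter + j:05d}")
        for j, iv in enumerate(fresh_iv)
    ]
    m2 = max(0, math.ceil(config.indirect_fraction * config.n_pos) - inherited_indirect)
    m2 = min(m2, n_fresh)
    ind2 = set(rng.choice(n_fresh, size=m2, replace=False).tolist()) if m2 else set()
    for j, iv in enumerate(fresh_iv):
        cls = "indirect" if j in ind2 else "direct"
        rep2_iv.append(iv)
        cls2.append(cls)
        _plant_peak(arr, iv, cls, config, rng, records, "rep2")

    # --- matched background ---------------------------------------------
    lengths_bg = _sample_lengths(config, config.n_bg, rng)
    bg_iv = place_random_intervals(
        lengths_bg,
        allowed,
        rng,
        exclude=list(rep1_iv) + rep2_iv,
        name_prefix="bg",
    )
    for iv in bg_iv:
        taken: list[tuple[int, int]] = []
        for pwm, _, leak in config.cofactors:
            if rng.random() < leak:
                strand = "+" if rng.random() < 0.5 else "-"
                off = _plant_into(arr, iv, pwm, strand, rng, taken)
                records.append(
                    {
                        "peak_id": iv.id,
                        "set": "background",
                        "motif_id": pwm.id,
                        "offset": off,
                        "strand": strand,
                    }
                )

    shared_rep2_names = {f"rep2_{c:05d}" for c in range(n_shared)}
    for name, ivs, clss in (
        ("rep1", rep1_iv, cls1),
        ("rep2", rep2_iv, cls2),
        ("background", bg_iv, ["background"] * len(bg_iv)),
    ):
        for j, (iv, cls) in enumerate(zip(ivs, clss)):
            shared = (
                j in shared_set if name == "rep1" else iv.id in shared_rep2_names
            )
            peak_rows.append(
                {
                    "peak_id": iv.id,
                    "set": name,
                    "cls": cls,
                    "shared": bool(shared),
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                }
            )

    truth = SyntheticTruth(
        plantings=pd.DataFrame(
            records, columns=["peak_id", "set", "motif_id", "offset", "strand"]
        ),
        peaks=pd.DataFrame(
            peak_rows, columns=["peak_id", "set", "cls", "shared", "chrom", "start", "end"]
        ),
    )
    chromosomes = {c: "".join(a) for c, a in genome.items()}
    return SyntheticDataset(
        config=config,
        chromosomes=chromosomes,
        allowed=allowed,
        rep1=PeakSet("rep1", rep1_iv),
        rep2=PeakSet("rep2", rep2_iv),
        background=PeakSet("background", bg_iv),
        truth=truth,
    )


def write_fasta(chromosomes: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Emit FASTA + BEDs + truth TSVs + MEME library + config JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "allowed": outdir / "allowed.bed",
        "rep1": outdir / "rep1.bed",
        "rep2": outdir / "rep2.bed",
        "background": outdir / "background.bed",
        "plantings": outdir / "truth_plantings.tsv",
        "peaks": outdir / "truth_peaks.tsv",
        "pwms": outdir / "pwms.meme",
        "config": outdir / "config.json",
    }
    write_fasta(ds.chromosomes, paths["genome"])
    write_bed(ds.allowed, paths["allowed"])
    write_bed(ds.rep1, paths["rep1"])
    write_bed(ds.rep2, paths["rep2"])
    write_bed(ds.background, paths["background"])
    ds.truth.plantings.to_csv(paths["plantings"], sep="\t", index=False)
    ds.truth.peaks.to_csv(paths["peaks"], sep="\t", index=False)
    write_meme(ds.config.all_pwms(), paths["pwms"])
    cfg = ds.config.scalars()
    cfg["anchor_id"] = ds.config.anchor.id
    cfg["cofactor_ids"] = [p.id for p, _, _ in ds.config.cofactors]
    cfg["decoy_ids"] = [p.id for p in ds.config.decoys]
    with open(paths["config"], "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
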