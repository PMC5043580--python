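"""PWM model, format readers, log-likelihood scanning and similarity."""

import math

import numpy as np
import pytest

from motifgrammar import (
    BackgroundModel,
    PWM,
    information_content,
    log_likelihood_score,
    pwm_similarity,
    read_pwm_library,
    reverse_complement,
    scan_sequence,
    write_meme,
)
from motifgrammar.motifs import MotifParseError, count_occurrences
from motifgrammar.simulate import revcomp

from conftest import random_pwm_probs

MEME_TEXT = """MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF m1 first
letter-probability matrix: alength= 4 w= 2 nsites= 20 E= 0
1.0 0.0 0.0 0.0
0.0 1.0 0.0 0.0
"""

JASPAR_TEXT = """>MA0001.1 AC2
A [ 4 0 ]
C [ 0 4 ]
G [ 0 0 ]
T [ 0 0 ]
"""

TRANSFAC_TEXT = """VV  test
XX
//
ID  motifA
BF  none
P0      A      C      G      T
01      4      0      0      0      X
02      0      4      0      0      X
03      0      0      4      0      X
XX
//
"""


@pytest.mark.parametrize(
    "text,suffix,fmt,width,source",
    [
        (MEME_TEXT, "lib.meme", None, 2, "meme"),
        (JASPAR_TEXT, "lib.jaspar", None, 2, "jaspar"),
        (TRANSFAC_TEXT, "lib.transfac", None, 3, "transfac"),
        (JASPAR_TEXT, "lib.weird", "jaspar_pfm", 2, "jaspar"),
    ],
)
def test_read_pwm_library_formats(tmp_path, text, suffix, fmt, width, source):
    path = tmp_path / suffix
    path.write_text(text)
    pwms = read_pwm_library(path, format=fmt, pseudocount=0.0)
    assert len(pwms) == 1
    p = pwms[0]
    assert p.width == width
    assert p.source == source
    np.testing.assert_allclose(p.probs.sum(axis=1), 1.0, atol=1e-9)
    # counts normalize to an exact one-hot AC(G) consensus with zero pseudocount
    np.testing.assert_allclose(p.probs[0], [1, 0, 0, 0])
    np.testing.assert_allclose(p.probs[1], [0, 1, 0, 0])


def test_read_pwm_pseudocount_smooths(tmp_path):
    path = tmp_path / "lib.jaspar"
    path.write_text(JASPAR_TEXT)
    (p,) = read_pwm_library(path, pseudocount=1.0)
    np.testing.assert_allclose(p.probs[0], [5 / 8, 1 / 8, 1 / 8, 1 / 8])


def test_read_pwm_zero_column_rejected(tmp_path):
    path = tmp_path / "bad.jaspar"
    path.write_text(">M0 zero\nA [ 0 1 ]\nC [ 0 0 ]\nG [ 0 0 ]\nT [ 0 1 ]\n")
    with pytest.raises(MotifParseError, match="all-zero"):
        read_pwm_library(path, pseudocount=0.0)
    # a pseudocount rescues the degenerate position
    (p,) = read_pwm_library(path, pseudocount=0.1)
    np.testing.assert_allclose(p.probs[0], [0.25, 0.25, 0.25, 0.25])


def test_read_pwm_duplicate_and_malformed(tmp_path):
    dup = tmp_path / "dup.jaspar"
    dup.write_text(JASPAR_TEXT + "\n" + JASPAR_TEXT)
    with pytest.raises(MotifParseError, match="duplicate"):
        read_pwm_library(dup)
    bad = tmp_path / "bad.meme"
    bad.write_text(MEME_TEXT.replace("0.0 1.0", "0.0 oops"))
    with pytest.raises(MotifParseError):
        read_pwm_library(bad)
    with pytest.raises(MotifParseError, match="format"):
        read_pwm_library(tmp_path / "x.unknown")


def test_meme_roundtrip(tmp_path, random_pwms):
    path = tmp_path / "out.meme"
    write_meme(random_pwms, path)
    back = read_pwm_library(path, pseudocount=0.0)
    assert [p.id for p in back] == [p.id for p in random_pwms]
    for a, b in zip(random_pwms, back):
        np.testing.assert_allclose(a.probs, b.probs, atol=1e-5)


def test_pwm_validation():
    with pytest.raises(ValueError, match="sum"):
        PWM("bad", [[0.5, 0.1, 0.1, 0.1]])
    with pytest.raises(ValueError, match="negative|sum"):
        PWM("bad", [[1.2, -0.2, 0.0, 0.0]])
    with pytest.raises(ValueError):
        PWM("bad", np.empty((0, 4)))


def test_reverse_complement_basics():
    a = PWM("a", [[1, 0, 0, 0]])
    assert reverse_complement(a).probs.tolist() == [[0, 0, 0, 1]]
    ac = PWM("ac", [[1, 0, 0, 0], [0, 1, 0, 0]])
    assert reverse_complement(ac).consensus() == "GT"


def test_reverse_complement_involution(rng):
    for _ in range(100):
        p = PWM("p", random_pwm_probs(rng, int(rng.integers(1, 15))))
        np.testing.assert_allclose(
            reverse_complement(reverse_complement(p)).probs, p.probs
        )
        np.testing.assert_allclose(
            reverse_complement(p).probs.sum(axis=1), 1.0, atol=1e-6
        )


def test_log_likelihood_score(uniform_bg, pwm_a07):
    uni = PWM("u", np.full((3, 4), 0.25))
    assert log_likelihood_score(uni, "ACG", uniform_bg) == pytest.approx(0.0)
    # 2 * log2(0.7 / 0.25), hand arithmetic
    assert log_likelihood_score(pwm_a07, "AA", uniform_bg) == pytest.approx(
        2.9708536543404835
    )
    assert log_likelihood_score(pwm_a07, "AN", uniform_bg) == -math.inf
    with pytest.raises(ValueError, match="length"):
        log_likelihood_score(pwm_a07, "AAA", uniform_bg)


def test_scan_sequence_polya(uniform_bg, pwm_a07):
    hits = scan_sequence(pwm_a07, "A" * 20, uniform_bg, threshold=2.0)
    assert len(hits) == 19
    assert all(h.strand == "+" for h in hits)
    assert [h.position for h in hits] == list(range(19))
    assert scan_sequence(pwm_a07, "", uniform_bg, threshold=2.0) == []
    assert scan_sequence(pwm_a07, "A" * 20, uniform_bg, threshold=3.1) == []


def _oracle_scan(pwm, seq, bg, threshold):
    """Independent window-by-window scorer (string arithmetic only)."""
    out = []
    w = pwm.width
    for pos in range(len(seq) - w + 1):
        window = seq[pos : pos + w]
        fwd = log_likelihood_score(pwm, window, bg)
        if fwd >= threshold:
            out.append((pos, "+", fwd))
        rev = log_likelihood_score(pwm, revcomp(window), bg)
        if rev >= threshold:
            out.append((pos, "-", rev))
    return sorted(out)


def test_scanner_matches_oracle(rng, uniform_bg):
    bgs = [uniform_bg, BackgroundModel(np.array([0.4, 0.1, 0.2, 0.3]))]
    for i in range(30):
        pwm = PWM("p", random_pwm_probs(rng, int(rng.integers(2, 10))))
        seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(0, 120))))
        bg = bgs[i % 2]
        got = sorted(
            (h.position, h.strand, h.score)
            for h in scan_sequence(pwm, seq, bg, threshold=1.0)
        )
        expect = _oracle_scan(pwm, seq, bg, threshold=1.0)
        assert [(p, s) for p, s, _ in got] == [(p, s) for p, s, _ in expect]
        np.testing.assert_allclose(
            [s for *_, s in got], [s for *_, s in expect], atol=1e-9
        )


def test_strand_invariance(rng):
    bg = BackgroundModel(np.array([0.35, 0.15, 0.2, 0.3]))  # asymmetric
    for _ in range(20):
        pwm = PWM("p", random_pwm_probs(rng, 6))
        seq = "".join(rng.choice(list("ACGT"), size=150))
        n1 = len(scan_sequence(pwm, seq, bg, threshold=1.0))
        n2 = len(scan_sequence(pwm, revcomp(seq), bg, threshold=1.0))
        assert n1 == n2


def test_scan_handles_n_and_merge(uniform_bg, pwm_a07):
    hits = scan_sequence(pwm_a07, "AANAA", uniform_bg, threshold=2.0)
    assert [h.position for h in hits] == [0, 3]
    merged = scan_sequence(
        pwm_a07, "A" * 20, uniform_bg, threshold=2.0, merge_overlaps=True
    )
    assert len(merged) == 10  # non-overlapping width-2 windows in 20 bp


def test_count_occurrences_matches_scan(rng, uniform_bg):
    pwms = [PWM(f"p{i}", random_pwm_probs(rng, int(rng.integers(2, 8)))) for i in range(5)]
    seqs = ["".join(rng.choice(list("ACGT"), size=int(rng.integers(0, 100)))) for _ in range(8)]
    counts = count_occurrences(pwms, seqs, uniform_bg, threshold=1.0)
    for i, s in enumerate(seqs):
        for j, p in enumerate(pwms):
            assert counts[i, j] == len(scan_sequence(p, s, uniform_bg, threshold=1.0))


def test_information_content(uniform_bg):
    assert information_content(PWM("u", np.full((5, 4), 0.25)), uniform_bg) == 0.0
    assert information_content(PWM("h", [[1, 0, 0, 0]]), uniform_bg) == pytest.approx(2.0)
    col = PWM("c", [[0.7, 0.1, 0.1, 0.1]])
    assert information_content(col, uniform_bg) == pytest.approx(0.6432203505529606)


def test_pwm_similarity_examples():
    a = PWM("a", [[1, 0, 0, 0]] * 4)
    c = PWM("c", [[0, 1, 0, 0]] * 4)
    assert pwm_similarity(a, a) == pytest.approx(1.0)
    assert pwm_similarity(a, reverse_complement(a)) == pytest.approx(1.0)
    assert pwm_similarity(a, c) == pytest.approx(-1 / 3)


def test_pwm_similarity_symmetric_and_bounded(rng):
    for _ in range(30):
        a = PWM("a", random_pwm_probs(rng, int(rng.integers(4, 12))))
        b = PWM("b", random_pwm_probs(rng, int(rng.integers(4, 12))))
        s1, s2 = pwm_similarity(a, b), pwm_similarity(b, a)
        assert s1 == pytest.approx(s2, abs=1e-12)
        assert -1.0 <= s1 <= 1.0
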