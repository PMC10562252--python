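"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from clonarch.variants import VariantCall


def brute_force_microsatellite(
    window: str,
    span_start: int,
    span_end: int,
    min_score: int = 8,
    seed_length: int = 8,
    min_repeats: int = 2,
    mismatch_penalty: int = 1,
    max_motif: int = 6,
):
    """Exhaustive tandem-repeat scan: enumerate every (motif length, start,
    end) interval, score it against the period-shifted sequence, and return
    the best annotation tuple (score, length, motif, start) or None.

    Independent of the package's seed-and-extend scanner; shares only the
    scoring definition.
    """
    window = window.upper()
    n = len(window)
    best = None
    for m in range(1, max_motif + 1):
        if n < 2 * m:
            continue
        w = np.array(
            [
                1 if window[x] == window[x - m] and window[x] in "ACGT" else -mismatch_penalty
                for x in range(m, n)
            ]
        )
        nw = len(w)
        match = w == 1
        L = max(1, seed_length - m)
        ok = np.array(
            [bool(match[t : t + L].all()) for t in range(nw - L + 1)], dtype=bool
        )
        if not ok.any():
            continue
        okc = np.concatenate([[0], np.cumsum(ok)])
        P = np.concatenate([[0], np.cumsum(w)])
        for i in range(nw):
            if i >= span_end:  # region [i, j+m) cannot overlap the span
                break
            jmin = max(i + (min_repeats - 1) * m, i + 1, span_start - m + 1)
            for j in range(jmin, nw + 1):
                # seed inside [i, j): some t in [i, j - L] starts L matches
                hi = j - L  # <= len(ok) - 1 because j <= nw
                if hi < i or okc[hi + 1] - okc[i] == 0:
                    continue
                score = m + int(P[j] - P[i])
                if score < min_score:
                    continue
                cand = (score, -m, j + m - i, -i)
                if best is None or cand > best[0]:
                    best = (cand, i, j, m)
    if best is None:
        return None
    (score, _, length, _), i, j, m = best
    return (score, length, window[i : i + m], i)


def random_window(rng: np.random.Generator, n: int = 60, repeat_prob: float = 0.6) -> str:
    """Random sequence window; with probability ``repeat_prob`` a tandem
    repeat (possibly with one mismatch) is planted somewhere inside."""
    seq = list(rng.choice(list("ACGT"), size=n))
    if rng.random() < repeat_prob:
        m = int(rng.integers(1, 7))
        motif = "".join(rng.choice(list("ACGT"), size=m))
        copies = int(rng.integers(2, max(3, 20 // m)))
        repeat = list(motif * copies)
        if len(repeat) > 4 and rng.random() < 0.4:  # imperfect repeat
            repeat[int(rng.integers(1, len(repeat) - 1))] = str(rng.choice(list("ACGT")))
        start = int(rng.integers(0, max(1, n - len(repeat))))
        seq[start : start + len(repeat)] = repeat[: n - start]
    return "".join(seq)


def snv(chrom="chr1", pos=100, ref="C", alt="T", sample="S1", animal="A1", callers=(), **kw):
    return VariantCall(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        sample_id=sample,
        animal_id=animal,
        callers=frozenset(callers),
        **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230914)
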