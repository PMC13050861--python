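"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's own algorithms: the SSR oracle
enumerates every (position, unit length) window; the AMOVA oracle evaluates
the double sums literally; the UPGMA oracle is scipy's average linkage.
"""

from __future__ import annotations

import numpy as np


def repeat_rich_sequence(rng: np.random.Generator, length: int, n_planted: int = 120) -> str:
    """AT-skewed random background with planted tandem runs of unit 1-6.

    Planted runs sit at random positions with repeat counts straddling the
    detection thresholds, so the scanner sees hits, near-misses and
    overlapping phases.
    """
    base = rng.choice(list("ACGT"), size=length, p=[0.35, 0.15, 0.15, 0.35])
    seq = list("".join(base))
    for _ in range(n_planted):
        u = int(rng.integers(1, 7))
        motif = "".join(rng.choice(list("ACGT"), size=u))
        reps = int(rng.integers(3, 16))
        run = motif * reps
        start = int(rng.integers(0, length - len(run)))
        seq[start : start + len(run)] = run
    return "".join(seq)


def brute_force_ssrs(seq: str, thresholds: dict[int, int]) -> set[tuple]:
    """All maximal tandem runs as (start, end, unit_len, motif) tuples.

    A window qualifies if the motif is primitive, repeats >= threshold times,
    cannot be extended by another full unit on the right, and is the leftmost
    phase of its run (s[start-1] != s[start+u-1], or a boundary/non-ACGT
    character sits at start-1).
    """
    out = set()
    n = len(seq)
    acgt = set("ACGT")

    def primitive(m: str) -> bool:
        for d in range(1, len(m)):
            if len(m) % d == 0 and m == m[:d] * (len(m) // d):
                return False
        return True

    for u, min_rep in thresholds.items():
        for start in range(n - u * min_rep + 1):
            motif = seq[start : start + u]
            if not set(motif) <= acgt or not primitive(motif):
                continue
            reps = 1
            while (
                start + (reps + 1) * u <= n
                and seq[start + reps * u : start + (reps + 1) * u] == motif
            ):
                reps += 1
            if reps < min_rep:
                continue
            # leftmost phase: extending one character left must break the period
            if start > 0 and seq[start - 1] in acgt and seq[start - 1] == seq[start + u - 1]:
                continue
            out.add((start, start + reps * u, u, motif))
    return out


def amova_sums_by_hand(d: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) via the literal double sums over squared d."""
    n = len(groups)
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += d[i, j] ** 2
    ss_total /= n
    ss_within = 0.0
    for g in set(groups.tolist()):
        idx = [i for i in range(n) if groups[i] == g]
        acc = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                acc += d[idx[a], idx[b]] ** 2
        ss_within += acc / len(idx)
    return ss_total, ss_within


def insilico_pcr_hits(fwd: str, rev_rc: str, sequences) -> int:
    """Count productive amplicons by scanning every index pair."""
    hits = 0
    for _, seq in sequences:
        for i in range(len(seq) - len(fwd) + 1):
            if seq[i : i + len(fwd)] != fwd:
                continue
            for j in range(i, len(seq) - len(rev_rc) + 1):
                if seq[j : j + len(rev_rc)] != rev_rc:
                    continue
                product = j + len(rev_rc) - i
                if 100 <= product <= 300:
                    hits += 1
    return hits
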