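"""SSR (microsatellite) mining from transcript FASTA and primer filtering.

Detects maximal perfect tandem repeats with unit length 1-6 bp at the usual
EST-SSR thresholds (mono >= 10 repeats, di >= 6, tri- to hexa- >= 5), groups
motifs into strand/phase-invariant canonical classes, summarizes counts and
percentages per repeat type, and screens candidate primer pairs against the
standard design constraints (length 18-27 bp, GC 40-80%, Tm 58-65 C with
pair difference <= 2 C, product 100-300 bp) plus an in-silico PCR uniqueness
check.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp, gc_fraction

DEFAULT_THRESHOLDS: dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

PRIMER_LEN = (18, 27)
PRIMER_GC = (40.0, 80.0)
PRIMER_TM = (58.0, 65.0)
PRIMER_DTM = 2.0
PRODUCT_SIZE = (100, 300)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

__all__ = [
    "SSRLocus",
    "PrimerPair",
    "MotifSummary",
    "DEFAULT_THRESHOLDS",
    "scan_ssrs",
    "scan_sequence",
    "canonical_motif",
    "summarize_motifs",
    "repeat_type_percentages",
    "filter_primer_pairs",
    "insilico_pcr_unique",
    "read_fasta",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file (wrapped or unwrapped)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq).upper()))
    if not records and Path(path).stat().st_size > 0:
        raise ValueError(f"no FASTA records parsed from {path}")
    return records


def _is_primitive(motif: str) -> bool:
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def reverse_complement(seq: str) -> str:
    if not set(seq) <= set("ACGT"):
        raise ValueError(f"non-ACGT character in {seq!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_motif(motif: str) -> str:
    """Class representative: lexicographic minimum over all cyclic rotations
    of the motif and of its reverse complement (strand- and phase-invariant).
    """
    if not 1 <= len(motif) <= 6:
        raise ValueError("motif length must be 1-6")
    rc = reverse_complement(motif)
    n = len(motif)
    candidates = [motif[i:] + motif[:i] for i in range(n)]
    candidates += [rc[i:] + rc[:i] for i in range(n)]
    return min(candidates)


@dataclass(frozen=True)
class SSRLocus:
    seq_id: str
    start: int       # 0-based inclusive
    end: int         # 0-based exclusive
    motif: str
    canonical: str
    unit_len: int
    n_repeats: int


def scan_sequence(
    seq_id: str, seq: str, thresholds: Mapping[int, int] = DEFAULT_THRESHOLDS
) -> list[SSRLocus]:
    """All maximal perfect tandem runs in one sequence meeting thresholds.

    A run is reported once, at its smallest period (primitive motif); any
    non-ACGT character breaks repeat runs.  Results sorted by start.
    """
    seq = seq.upper()
    loci: list[SSRLocus] = []
    # split into pure-ACGT segments; offsets preserved
    for seg_match in re.finditer(r"[ACGT]+", seq):
        seg = seg_match.group(0)
        off = seg_match.start()
        for u, min_rep in sorted(thresholds.items()):
            pat = re.compile(r"(.{%d})\1{%d,}" % (u, min_rep - 1))
            pos = 0
            while True:
                m = pat.search(seg, pos)
                if m is None:
                    break
                motif = m.group(1)
                run_len = m.end() - m.start()
                n_rep = run_len // u
                if _is_primitive(motif):
                    loci.append(
                        SSRLocus(
                            seq_id=seq_id,
                            start=off + m.start(),
                            end=off + m.start() + n_rep * u,
                            motif=motif,
                            canonical=canonical_motif(motif),
                            unit_len=u,
                            n_repeats=n_rep,
                        )
                    )
                pos = m.end() - (u - 1) if u > 1 else m.end()
    loci.sort(key=lambda l: (l.start, l.unit_len))
    return loci


def scan_ssrs(
    sequences: Iterable[tuple[str, str]],
    thresholds: Mapping[int, int] = DEFAULT_THRESHOLDS,
) -> list[SSRLocus]:
    """Scan multiple (id, sequence) records; loci sorted by (seq_id, start)."""
    out: list[SSRLocus] = []
    for seq_id, seq in sequences:
        out.extend(scan_sequence(seq_id, seq, thresholds))
    out.sort(key=lambda l: (l.seq_id, l.start, l.unit_len))
    return out


def _pct(numer: int, denom: int) -> float:
    """Percentage rounded half-up to 2 decimals, matching report style."""
    return float(
        (Decimal(numer) * 100 / Decimal(denom)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def repeat_type_percentages(counts_by_unit: Mapping[int, int]) -> pd.DataFrame:
    """Count and percent-of-total per repeat type (unit length)."""
    total = sum(counts_by_unit.values())
    rows = [
        {"unit_len": u, "count": c, "percent": _pct(c, total) if total else float("nan")}
        for u, c in sorted(counts_by_unit.items())
    ]
    df = pd.DataFrame(rows).set_index("unit_len")
    df.attrs["total"] = total
    return df


@dataclass
class MotifSummary:
    by_unit: pd.DataFrame    # unit_len -> count, percent of total
    by_class: pd.DataFrame   # (unit_len, canonical) -> count, percent within unit
    total: int

    def dominant_motifs(self, unit_len: int, top: int = 5) -> pd.DataFrame:
        sub = self.by_class[self.by_class.index.get_level_values("unit_len") == unit_len]
        return sub.sort_values("count", ascending=False).head(top)


def summarize_motifs(loci: list[SSRLocus]) -> MotifSummary:
    counts_by_unit: dict[int, int] = {}
    counts_by_class: dict[tuple[int, str], int] = {}
    for locus in loci:
        counts_by_unit[locus.unit_len] = counts_by_unit.get(locus.unit_len, 0) + 1
        key = (locus.unit_len, locus.canonical)
        counts_by_class[key] = counts_by_class.get(key, 0) + 1
    total = len(loci)
    by_unit = repeat_type_percentages(counts_by_unit) if counts_by_unit else pd.DataFrame(
        columns=["count", "percent"], index=pd.Index([], name="unit_len")
    )
    rows = []
    for (u, canon), c in sorted(counts_by_class.items()):
        rows.append(
            {
                "unit_len": u,
                "canonical": canon,
                "count": c,
                "percent_within_unit": _pct(c, counts_by_unit[u]),
            }
        )
    by_class = (
        pd.DataFrame(rows).set_index(["unit_len", "canonical"])
        if rows
        else pd.DataFrame(columns=["count", "percent_within_unit"])
    )
    return MotifSummary(by_unit, by_class, total)


def primer_tm(seq: str) -> float:
    """Nearest-neighbor Tm at 50 mM monovalent salt, 0.25 uM oligo."""
    return float(MeltingTemp.Tm_NN(Seq(seq), Na=50, dnac1=250, dnac2=0))


@dataclass
class PrimerPair:
    forward_seq: str
    reverse_seq: str
    product_size: int
    target_locus: SSRLocus | None = None
    tm_f: float | None = None
    tm_r: float | None = None
    gc_f: float | None = None
    gc_r: float | None = None

    def __post_init__(self) -> None:
        self.forward_seq = self.forward_seq.upper()
        self.reverse_seq = self.reverse_seq.upper()
        if self.tm_f is None:
            self.tm_f = primer_tm(self.forward_seq)
        if self.tm_r is None:
            self.tm_r = primer_tm(self.reverse_seq)
        if self.gc_f is None:
            self.gc_f = gc_fraction(self.forward_seq) * 100.0
        if self.gc_r is None:
            self.gc_r = gc_fraction(self.reverse_seq) * 100.0


def primer_violations(pair: PrimerPair) -> list[str]:
    """Reason codes for every violated design constraint (empty = accepted)."""
    reasons = []
    for seq in (pair.forward_seq, pair.reverse_seq):
        if not PRIMER_LEN[0] <= len(seq) <= PRIMER_LEN[1]:
            reasons.append("length")
            break
    for gc in (pair.gc_f, pair.gc_r):
        if not PRIMER_GC[0] <= gc <= PRIMER_GC[1]:
            reasons.append("gc")
            break
    for tm in (pair.tm_f, pair.tm_r):
        if not PRIMER_TM[0] <= tm <= PRIMER_TM[1]:
            reasons.append("tm")
            break
    if abs(pair.tm_f - pair.tm_r) > PRIMER_DTM:
        reasons.append("dTm > 2")
    if not PRODUCT_SIZE[0] <= pair.product_size <= PRODUCT_SIZE[1]:
        reasons.append("product_size")
    return reasons


def filter_primer_pairs(
    candidates: Iterable[PrimerPair],
) -> tuple[list[PrimerPair], list[tuple[PrimerPair, list[str]]]]:
    """Split candidates into (accepted, rejected-with-reasons)."""
    accepted, rejected = [], []
    for pair in candidates:
        reasons = primer_violations(pair)
        if reasons:
            rejected.append((pair, reasons))
        else:
            accepted.append(pair)
    return accepted, rejected


def insilico_pcr_unique(
    pair: PrimerPair, sequences: Iterable[tuple[str, str]]
) -> bool:
    """True iff the primer pair amplifies exactly one productive site.

    A productive site is a forward-primer match followed downstream by a
    match of the reverse complement of the reverse primer, with total
    product length in the allowed range.  More than one such site anywhere
    in the sequence set (including within one sequence) fails uniqueness.
    """
    fwd = pair.forward_seq
    rev_rc = reverse_complement(pair.reverse_seq)
    lo, hi = PRODUCT_SIZE
    hits = 0
    for _, seq in sequences:
        f_pos = [m.start() for m in re.finditer(re.escape(fwd), seq)]
        r_pos = [m.start() for m in re.finditer(re.escape(rev_rc), seq)]
        for fp in f_pos:
            for rp in r_pos:
                product = rp + len(rev_rc) - fp
                if fp <= rp and lo <= product <= hi:
                    hits += 1
                    if hits > 1:
                        return False
    return hits == 1


def loci_to_table(loci: list[SSRLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "seq_id": l.seq_id,
                "start": l.start,
                "end": l.end,
                "motif": l.motif,
                "canonical_motif": l.canonical,
                "unit_len": l.unit_len,
                "n_repeats": l.n_repeats,
            }
            for l in loci
        ]
    )


def table_to_loci(df: pd.DataFrame) -> list[SSRLocus]:
    return [
        SSRLocus(
            seq_id=str(r.seq_id),
            start=int(r.start),
            end=int(r.end),
            motif=str(r.motif),
            canonical=str(r.canonical_motif),
            unit_len=int(r.unit_len),
            n_repeats=int(r.n_repeats),
        )
        for r in df.itertuples()
    ]
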