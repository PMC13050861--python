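"""Binary band-presence matrices and per-marker diversity statistics.

Dominant markers (SSR bands scored on gels) yield presence/absence data:
each band is a binary locus scored 1 (present), 0 (absent) or -9 (unreadable,
treated as missing).  Bands are grouped into markers (primer pairs); a marker
is treated as one multi-allelic locus whose "allele" frequencies are the
normalized band presence counts.  On that frequency vector the classical
diversity indices are computed: observed alleles Na, effective alleles
Ne = 1/sum(p^2), gene diversity H = 1 - sum(p^2), Shannon's information index
I = -sum(p ln p), and Botstein's polymorphism information content
PIC = 1 - sum(p^2) - sum_{i<j} 2 p_i^2 p_j^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -9

__all__ = [
    "MISSING",
    "BandMatrix",
    "MarkerDiversity",
    "read_band_matrix",
    "write_band_matrix",
    "marker_band_frequencies",
    "diversity_stats",
    "dataset_diversity_report",
]


class BandMatrixError(ValueError):
    """Raised for malformed band matrices."""


@dataclass
class BandMatrix:
    """Accessions x band-loci table of {0, 1, -9} values.

    Band identifiers follow the ``<marker>_<index>`` convention so the
    band-to-marker grouping is recoverable from the header alone; an explicit
    mapping can be supplied instead (e.g. when marker names contain ``_``).
    """

    values: pd.DataFrame
    marker_of_band: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.values.to_numpy()
        bad = ~np.isin(vals, (0, 1, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise BandMatrixError(
                f"invalid value {vals[i, j]!r} at accession "
                f"{self.values.index[i]!r}, band {self.values.columns[j]!r}"
            )
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise BandMatrixError(f"duplicate accession id {dup!r}")
        if not self.marker_of_band:
            self.marker_of_band = {
                b: b.rsplit("_", 1)[0] for b in self.values.columns
            }
        missing_map = set(self.values.columns) - set(self.marker_of_band)
        if missing_map:
            raise BandMatrixError(f"bands without marker mapping: {sorted(missing_map)[:3]}")
        self.values = self.values.astype(np.int64)

    @property
    def accession_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def band_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_accessions(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    @property
    def marker_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.values.columns:
            seen.setdefault(self.marker_of_band[b], None)
        return list(seen)

    def bands_of_marker(self, marker_id: str) -> list[str]:
        return [b for b in self.values.columns if self.marker_of_band[b] == marker_id]

    def validate_qc(self) -> None:
        """Reject rows/columns that are entirely missing."""
        vals = self.values.to_numpy()
        row_all = (vals == MISSING).all(axis=1)
        if row_all.any():
            raise BandMatrixError(
                f"accession {self.values.index[int(np.argmax(row_all))]!r} entirely missing"
            )
        col_all = (vals == MISSING).all(axis=0)
        if col_all.any():
            raise BandMatrixError(
                f"band {self.values.columns[int(np.argmax(col_all))]!r} entirely missing"
            )


def write_band_matrix(matrix: BandMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="accession")


def read_band_matrix(path: str | Path, marker_map: str | Path | None = None) -> BandMatrix:
    """Read a TSV band matrix; marker grouping from band ids or a sidecar.

    The sidecar, if given, is a two-column TSV ``band<TAB>marker``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        nonnum = pd.to_numeric(df[col], errors="coerce")
        if nonnum.isna().any():
            row = df.index[int(np.argmax(nonnum.isna().to_numpy()))]
            raise BandMatrixError(f"non-numeric value at accession {row!r}, band {col!r}")
    mapping: dict[str, str] = {}
    if marker_map is not None:
        side = pd.read_csv(marker_map, sep="\t", header=None, names=["band", "marker"])
        mapping = dict(zip(side["band"].astype(str), side["marker"].astype(str)))
    return BandMatrix(df.astype(np.int64), mapping)


def marker_band_frequencies(matrix: BandMatrix, marker_id: str) -> pd.Series:
    """Normalized presence-count frequencies for one marker's bands.

    Missing cells are excluded per band (pairwise deletion); bands never
    observed present are dropped.  Frequencies sum to 1.
    """
    bands = matrix.bands_of_marker(marker_id)
    if not bands:
        raise BandMatrixError(f"unknown marker {marker_id!r}")
    sub = matrix.values[bands].to_numpy()
    counts = (sub == 1).sum(axis=0).astype(float)
    keep = counts > 0
    if not keep.any():
        raise BandMatrixError(f"monomorphic-absent marker {marker_id!r}: no presences")
    counts = counts[keep]
    names = [b for b, k in zip(bands, keep) if k]
    return pd.Series(counts / counts.sum(), index=names, name=marker_id)


@dataclass(frozen=True)
class MarkerDiversity:
    marker_id: str
    Na: int
    Ne: float
    H: float
    I: float
    PIC: float


def diversity_stats(p: np.ndarray | pd.Series, marker_id: str = "") -> MarkerDiversity:
    """Diversity indices from an allele-frequency vector (sum 1, all > 0)."""
    freqs = np.asarray(p, dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency vector")
    if (freqs <= 0).any() or abs(freqs.sum() - 1.0) > 1e-8:
        raise ValueError("frequencies must be positive and sum to 1")
    sq = float(np.sum(freqs**2))
    # PIC = 1 - sum p^2 - sum_{i<j} 2 p_i^2 p_j^2 ; the cross term equals
    # ((sum p^2)^2 - sum p^4)
    pic = 1.0 - sq - (sq**2 - float(np.sum(freqs**4)))
    return MarkerDiversity(
        marker_id=marker_id,
        Na=int(freqs.size),
        Ne=1.0 / sq,
        H=1.0 - sq,
        I=float(-np.sum(freqs * np.log(freqs))),
        PIC=pic,
    )


def polymorphism_class(pic: float) -> str:
    """Botstein classes: high (>0.5), moderate (0.25-0.5), low (<0.25)."""
    if pic > 0.5:
        return "high"
    if pic >= 0.25:
        return "moderate"
    return "low"


def dataset_diversity_report(matrix: BandMatrix) -> pd.DataFrame:
    """Per-marker diversity table with a trailing mean/total row.

    The last row (index ``"mean"``) holds the across-marker means, with Na
    replaced by the mean alleles per marker (total Na / marker count, to one
    decimal in formatted output, full precision here).
    """
    rows = []
    for marker in matrix.marker_ids:
        p = marker_band_frequencies(matrix, marker)
        d = diversity_stats(p.to_numpy(), marker)
        rows.append(
            {
                "marker": marker,
                "Na": d.Na,
                "Ne": d.Ne,
                "H": d.H,
                "I": d.I,
                "PIC": d.PIC,
                "class": polymorphism_class(d.PIC),
            }
        )
    table = pd.DataFrame(rows).set_index("marker")
    means = table[["Na", "Ne", "H", "I", "PIC"]].mean()
    summary = means.to_dict()
    summary["class"] = ""
    table.loc["mean"] = summary
    table.attrs["total_Na"] = int(table["Na"].iloc[:-1].sum())
    table.attrs["n_markers"] = len(rows)
    table.attrs["mean_alleles_per_marker"] = round(
        table.attrs["total_Na"] / table.attrs["n_markers"], 1
    )
    return table
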