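"""Reading and writing phenotype and genotype tables.

Phenotype tables are CSV with columns ``strain, animal_id, age_wk``
plus the six parameters.  Genotype maps are TSV marker tables
(``marker, position_mb`` plus one allele column per strain, alleles
B = host, M = donor); runs of M alleles become half-open donor
intervals with breakpoints placed at the midpoint between flanking
discordant markers (conventional point estimate; ``outer_bounds``
switches to the conservative outer marker positions).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genmap import GenotypeMap
from .screen import PARAMETERS

__all__ = [
    "read_phenotype_table",
    "write_phenotype_table",
    "read_genotype_map",
    "write_genotype_map",
]

REQUIRED_COLUMNS = ("strain", "animal_id", "age_wk")


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a phenotype CSV.

    Checks: required columns present, parameter cells numeric, BV/TV a
    fraction in [0, 1], no duplicate (strain, animal_id).  Errors name
    the offending row (1-based data rows, excluding the header).
    """
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty phenotype file") from exc
    if len(table) == 0:
        raise ValueError(f"{path}: phenotype file has no data rows")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    params = [p for p in PARAMETERS if p in table.columns]
    if not params:
        raise ValueError(f"{path}: no parameter columns found (expect {PARAMETERS})")
    for p in params:
        numeric = pd.to_numeric(table[p], errors="coerce")
        bad = table.index[numeric.isna() & table[p].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value in column {p}, row {bad[0] + 1}"
            )
        table[p] = numeric
    if "BVTV" in table.columns:
        bad = table.index[(table["BVTV"] < 0) | (table["BVTV"] > 1)]
        if len(bad):
            raise ValueError(
                f"{path}: BVTV outside [0, 1] at row {bad[0] + 1} "
                f"(value {table.loc[bad[0], 'BVTV']})"
            )
    dup = table.duplicated(subset=["strain", "animal_id"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicate animal id at row {int(np.flatnonzero(dup)[0]) + 1}"
        )
    return table


def write_phenotype_table(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def read_genotype_map(
    path: str | Path,
    host: str | None = None,
    donor: str | None = None,
    outer_bounds: bool = False,
) -> GenotypeMap:
    """Parse a marker TSV into per-strain donor intervals.

    The chromosome length is taken as the last marker position.  A run
    of M alleles from marker i to j becomes the interval
    ``[mid(p[i-1], p[i]), mid(p[j], p[j+1]))`` (or the chromosome ends
    for terminal runs); ``outer_bounds`` uses the flanking discordant
    marker positions instead.  Host/donor parents default to the
    all-B / all-M columns when not named.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    for col in ("marker", "position_mb"):
        if col not in table.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    pos = table["position_mb"].to_numpy(float)
    if np.any(np.diff(pos) <= 0):
        raise ValueError(f"{path}: marker positions must be strictly increasing")
    strains = [c for c in table.columns if c not in ("marker", "position_mb")]
    if not strains:
        raise ValueError(f"{path}: no strain columns")
    length = float(pos[-1])
    intervals: dict[str, tuple] = {}
    for s in strains:
        alleles = table[s].astype(str).str.strip().to_numpy()
        bad = ~np.isin(alleles, ("B", "M"))
        if bad.any():
            raise ValueError(
                f"{path}: allele {alleles[np.flatnonzero(bad)[0]]!r} for strain "
                f"{s} is not B or M"
            )
        is_m = alleles == "M"
        ivs = []
        i = 0
        n = len(is_m)
        while i < n:
            if is_m[i]:
                j = i
                while j + 1 < n and is_m[j + 1]:
                    j += 1
                if outer_bounds:
                    a = 0.0 if i == 0 else float(pos[i - 1])
                    b = length if j == n - 1 else float(pos[j + 1])
                else:
                    a = 0.0 if i == 0 else float((pos[i - 1] + pos[i]) / 2)
                    b = length if j == n - 1 else float((pos[j] + pos[j + 1]) / 2)
                ivs.append((a, b))
                i = j + 1
            else:
                i += 1
        intervals[s] = tuple(ivs)
    if host is None:
        allb = [s for s in strains if not intervals[s]]
        host = allb[0] if allb else None
    if donor is None:
        allm = [s for s in strains if intervals[s] == ((0.0, length),)]
        donor = allm[0] if allm else None
    return GenotypeMap(
        chrom_length_mb=length,
        marker_positions_mb=tuple(map(float, pos)),
        intervals=intervals,
        host=host,
        donor=donor,
    )


def write_genotype_map(gmap: GenotypeMap, path: str | Path) -> None:
    """Write the marker TSV: allele M where the marker position falls
    inside a donor interval, B otherwise."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    L = gmap.chrom_length_mb
    rows = []
    for p in gmap.marker_positions_mb:
        row = {"marker": f"chr_{p:.3f}", "position_mb": p}
        for s in gmap.strains:
            # the terminal marker at L belongs to an interval ending at L
            inside = any(
                a <= p < b or (abs(p - L) < 1e-9 and abs(b - L) < 1e-9 and a <= p)
                for a, b in gmap.intervals[s]
            )
            row[s] = "M" if inside else "B"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
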