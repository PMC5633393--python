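"""Simulated consomic and subconsomic phenotype panels.

The consomic generator emulates a chromosome-substitution panel: 26
single-substitution strains (whole autosomes, four centromeric/
telomeric half-chromosomes, X, Y and the mitochondrial genome) plus
the host (B6) and donor (MSM) parents.  Each animal's value for a
parameter is the host mean, plus the substituted chromosome's effect,
plus independent Gaussian noise.  Epistasis enters through the donor
parent: the donor carries every substitution yet expresses only the
parental difference, so the summed single-substitution effects can
greatly exceed it.  The ``epistasis_coefficient`` sets that ratio —
auto-generated per-chromosome effects are scaled so their sum equals
``epistasis_coefficient x (donor mean - host mean)`` per parameter
(default 13.9, i.e. a 1390% nonadditivity index when every strain is
significant).

The subconsomic generator emulates a panel of strains carrying donor
fragments of a single chromosome.  A strain's mean is the host mean
plus the effects of every planted QTL whose block its donor intervals
cover, and its genotype is the corresponding marker-interval map.  The
default geometry yields ten blocks whose adjacent-pair structure
mirrors the real panel (including one pair that differs in two
non-adjacent blocks), with four planted QTL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import GenotypeMap

__all__ = [
    "PanelSpec",
    "SubconsomicSpec",
    "simulate_consomic_panel",
    "simulate_subconsomic_panel",
    "default_consomic_strains",
    "default_subconsomic_intervals",
    "paper_like_qtl",
    "bvtv_only_qtl",
]

# Host (B6) and donor (MSM) strain means at 10 wk, and per-parameter
# animal-to-animal noise SD.  Units: BVTV fraction, TbN 1/mm,
# ConnD 1/mm^3, TbSp mm, SMI -, TbTh mm.
CONTROL_MEANS_10WK = {
    "BVTV": 0.155, "TbN": 4.6, "ConnD": 160.0,
    "TbSp": 0.185, "SMI": 1.6, "TbTh": 0.034,
}
DONOR_MEANS_10WK = {
    "BVTV": 0.060, "TbN": 3.2, "ConnD": 75.0,
    "TbSp": 0.300, "SMI": 2.7, "TbTh": 0.031,
}
NOISE_SD_10WK = {
    "BVTV": 0.012, "TbN": 0.25, "ConnD": 18.0,
    "TbSp": 0.020, "SMI": 0.18, "TbTh": 0.002,
}

CONTROL_MEANS_6WK = {
    "BVTV": 0.120, "TbN": 4.0, "ConnD": 140.0,
    "TbSp": 0.210, "SMI": 1.9, "TbTh": 0.030,
}
NOISE_SD_6WK = {
    "BVTV": 0.008, "TbN": 0.15, "ConnD": 15.0,
    "TbSp": 0.015, "SMI": 0.15, "TbTh": 0.0015,
}


def default_consomic_strains() -> list[str]:
    """26 single-substitution strain labels: whole autosomes, four
    split chromosomes (centromeric/telomeric halves), X, Y, Mt."""
    split = {2, 6, 12, 13}
    labels: list[str] = []
    for c in range(1, 20):
        if c in split:
            labels += [f"C{c}C", f"C{c}T"]
        else:
            labels.append(f"C{c}")
    labels += ["CX", "Y", "Mt"]
    return labels


@dataclass(frozen=True)
class PanelSpec:
    """Consomic-panel simulation parameters.

    ``per_chromosome_effects`` maps strain -> {parameter: effect}; when
    None, effects are auto-generated (see module docstring).  The donor
    parent's mean is ``donor_mean`` regardless of the summed effects —
    that gap is the planted epistasis.
    """

    strains: tuple[str, ...] = tuple(default_consomic_strains())
    replicates_per_strain: int = 8
    control: str = "B6"
    donor: str = "MSM"
    control_mean: dict = field(default_factory=lambda: dict(CONTROL_MEANS_10WK))
    donor_mean: dict = field(default_factory=lambda: dict(DONOR_MEANS_10WK))
    per_chromosome_effects: dict | None = None
    epistasis_coefficient: float = 13.9
    noise_sd: dict = field(default_factory=lambda: dict(NOISE_SD_10WK))
    age_wk: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_strain < 2:
            raise ValueError("replicates_per_strain must be >= 2")
        if any(v <= 0 for v in self.noise_sd.values()):
            raise ValueError("noise_sd must be positive")
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("duplicate strain labels")
        if self.control in self.strains or self.donor in self.strains:
            raise ValueError("parents must not appear among consomic strains")


def _auto_effects(spec: PanelSpec, rng: np.random.Generator) -> dict:
    """Per-strain effects whose sum is epistasis_coefficient x the
    parental difference.

    One shared strain weight vector drives the five correlated
    parameters (BV/TV, Tb.N, Conn.D, Tb.Sp, SMI), reproducing the
    strong cross-parameter correlations of a real panel; Tb.Th gets
    independent small two-sided effects (it is uncorrelated with the
    rest and its strain values overshoot the parental range).  Weights
    stay inside (0, 1) x the parental difference so every strain mean
    lies between (or near) the parents, as observed in real panels.
    """
    n = len(spec.strains)
    lo, hi = 0.2, 0.87  # mean 0.535 ~ epistasis_coefficient / 26
    w = rng.uniform(lo, hi, size=n)
    w = w * (spec.epistasis_coefficient / w.sum())
    effects: dict[str, dict[str, float]] = {s: {} for s in spec.strains}
    for param in spec.control_mean:
        parental = spec.donor_mean[param] - spec.control_mean[param]
        if param == "TbTh":
            vals = rng.normal(0.0, 2.0 * spec.noise_sd.get(param, 0.0), size=n)
        else:
            vals = w * parental
        for s, v in zip(spec.strains, vals):
            effects[s][param] = float(v)
    return effects


def simulate_consomic_panel(spec: PanelSpec) -> pd.DataFrame:
    """Simulate per-animal phenotypes for the panel plus both parents.

    Returns a table with columns strain, animal_id, age_wk and one
    column per parameter.  Reproducible given the spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    effects = (
        spec.per_chromosome_effects
        if spec.per_chromosome_effects is not None
        else _auto_effects(spec, rng)
    )
    params = list(spec.control_mean)
    means: dict[str, dict[str, float]] = {
        spec.control: dict(spec.control_mean),
        spec.donor: dict(spec.donor_mean),
    }
    for s in spec.strains:
        means[s] = {
            p: spec.control_mean[p] + effects.get(s, {}).get(p, 0.0) for p in params
        }
    rows = []
    for s in [spec.control, spec.donor, *spec.strains]:
        for i in range(spec.replicates_per_strain):
            row = {"strain": s, "animal_id": f"{s}_{i + 1}", "age_wk": spec.age_wk}
            for p in params:
                row[p] = means[s][p] + rng.normal(0.0, spec.noise_sd[p])
            rows.append(row)
    return pd.DataFrame(rows)


# -- subconsomic panel -------------------------------------------------

# Chromosome-15-like geometry.  Length = the most telomeric marker; the
# internal breakpoints generate ten atomic blocks.
CHR_LENGTH_MB = 102.254
MARKER_POSITIONS_MB = (
    3.0, 6.64, 13.5, 21.75, 26.0, 32.35, 45.0,
    58.0, 71.63, 84.21, 90.76, 96.0, 102.254,
)
_L = CHR_LENGTH_MB


def default_subconsomic_intervals() -> dict[str, tuple[tuple[float, float], ...]]:
    """Eight donor-fragment strains plus both parents.

    Adjacent pairs in the optimal alignment each differ in one block,
    except Sub-5 vs C15 which differ in two non-adjacent blocks
    ([0, 6.64) and [21.75, 26.0)) — the panel's one ambiguous pair.
    """
    return {
        "B6": (),
        "Sub-10": ((90.76, _L),),
        "Sub-9": ((84.21, _L),),
        "Sub-8": ((71.63, _L),),
        "Sub-26": ((58.0, _L),),
        "Sub-25": ((6.64, 21.75), (58.0, _L)),
        "Sub-30": ((6.64, 21.75), (45.0, _L)),
        "Sub-11": ((6.64, 21.75), (32.35, _L)),
        "Sub-5": ((6.64, 21.75), (26.0, _L)),
        "C15": ((0.0, _L),),
    }


def paper_like_qtl() -> list[tuple[tuple[float, float], str, float]]:
    """Four planted QTL mirroring the real panel's architecture:
    Block2 raises Tb.Th, Block6 raises BV/TV, Block8 and Block10 lower
    BV/TV and Tb.N (donor-allele directions)."""
    return [
        ((6.64, 21.75), "TbTh", +0.006),
        ((45.0, 58.0), "BVTV", +0.030),
        ((71.63, 84.21), "BVTV", -0.035),
        ((71.63, 84.21), "TbN", -0.60),
        ((90.76, _L), "BVTV", -0.040),
        ((90.76, _L), "TbN", -0.70),
    ]


def bvtv_only_qtl() -> list[tuple[tuple[float, float], str, float]]:
    """Four planted single-block QTL on BV/TV alone (effects ~10x the
    SE of a strain mean), used for single-parameter recovery studies."""
    return [
        ((6.64, 21.75), "BVTV", +0.045),
        ((45.0, 58.0), "BVTV", +0.045),
        ((71.63, 84.21), "BVTV", -0.050),
        ((90.76, _L), "BVTV", -0.055),
    ]


@dataclass(frozen=True)
class SubconsomicSpec:
    """Subconsomic-panel simulation parameters.

    ``planted_qtl`` is a list of (block interval, parameter, signed
    effect); block intervals must have endpoints on the marker grid or
    chromosome ends.  A strain expresses an effect when its donor
    intervals cover the block.
    """

    chromosome_length_mb: float = CHR_LENGTH_MB
    marker_positions_mb: tuple[float, ...] = MARKER_POSITIONS_MB
    strain_intervals: dict = field(default_factory=default_subconsomic_intervals)
    planted_qtl: list = field(default_factory=paper_like_qtl)
    host: str = "B6"
    donor: str = "C15"
    control_mean: dict = field(default_factory=lambda: dict(CONTROL_MEANS_6WK))
    noise_sd: dict = field(default_factory=lambda: dict(NOISE_SD_6WK))
    replicates: int = 6
    age_wk: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if any(v <= 0 for v in self.noise_sd.values()):
            raise ValueError("noise_sd must be positive")
        grid = set(self.marker_positions_mb) | {0.0, self.chromosome_length_mb}
        for (a, b), param, eff in self.planted_qtl:
            if not np.isfinite(eff):
                raise ValueError("planted effect must be finite")
            for p in (a, b):
                if not any(abs(p - g) < 1e-9 for g in grid):
                    raise ValueError(
                        f"planted QTL endpoint {p} not on the marker grid"
                    )
            if param not in self.control_mean:
                raise ValueError(f"planted QTL parameter {param!r} unknown")


def simulate_subconsomic_panel(
    spec: SubconsomicSpec,
) -> tuple[GenotypeMap, pd.DataFrame]:
    """Simulate the genotype map and per-animal phenotypes.

    Strain mean = host mean + sum of planted effects whose block the
    strain's donor intervals cover; noise is i.i.d. Gaussian per
    parameter.  Reproducible given the spec seed.
    """
    gmap = GenotypeMap(
        chrom_length_mb=spec.chromosome_length_mb,
        marker_positions_mb=tuple(spec.marker_positions_mb),
        intervals={s: tuple(iv) for s, iv in spec.strain_intervals.items()},
        host=spec.host,
        donor=spec.donor,
    )
    rng = np.random.default_rng(spec.seed)
    params = list(spec.control_mean)
    rows = []
    for s in gmap.strains:
        shift = {p: 0.0 for p in params}
        for (a, b), param, eff in spec.planted_qtl:
            if gmap.covers(s, a, b):
                shift[param] += eff
        for i in range(spec.replicates):
            row = {"strain": s, "animal_id": f"{s}_{i + 1}", "age_wk": spec.age_wk}
            for p in params:
                row[p] = (
                    spec.control_mean[p] + shift[p] + rng.normal(0.0, spec.noise_sd[p])
                )
            rows.append(row)
    return gmap, pd.DataFrame(rows)
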