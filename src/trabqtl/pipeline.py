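"""End-to-end pipeline: simulate (optional) -> screen -> map blocks.

``run_pipeline`` glues the stages together, writes every report plus a
JSON provenance record (package version, seed, config hash), and is
byte-identical across runs with the same seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .genmap import assign_qtl, neighbor_tests, order_by_similarity, partition_blocks
from .io import (
    read_genotype_map,
    read_phenotype_table,
    write_genotype_map,
    write_phenotype_table,
)
from .panels import PanelSpec, SubconsomicSpec, simulate_consomic_panel, \
    simulate_subconsomic_panel
from .screen import dunnett_screen, nonadditivity_index, order_strains, spearman_matrix

log = logging.getLogger("trabqtl")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for a full run.

    When ``simulate`` is true the panels are generated from the seed;
    otherwise ``phenotype_csv`` (consomic), ``sub_phenotype_csv`` and
    ``genotype_tsv`` must point to existing files.
    """

    out_dir: str = "trabqtl_out"
    simulate: bool = True
    phenotype_csv: str | None = None
    sub_phenotype_csv: str | None = None
    genotype_tsv: str | None = None
    control: str = "B6"
    donor: str = "MSM"
    sub_host: str = "B6"
    sub_donor: str = "C15"
    alpha_screen: float = 0.05
    alpha_family: float = 0.05
    map_parameters: tuple[str, ...] = ("BVTV", "TbN", "TbTh")
    seed: int = 0

    def __post_init__(self) -> None:
        for a in (self.alpha_screen, self.alpha_family):
            if not 0 < a < 1:
                raise ValueError("alpha must be in (0, 1)")
        if not self.simulate:
            for name in ("phenotype_csv", "sub_phenotype_csv", "genotype_tsv"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"{name} is required when simulate is false")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: no such file {p!r}")


def _config_hash(config: PipelineConfig) -> str:
    payload = asdict(config)
    payload.pop("out_dir", None)  # hash the analysis config, not its location
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _dump_json(obj, path: Path, stamp: dict) -> None:
    payload = {"provenance": stamp, **obj}
    path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=str))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a dict of output paths.

    Any stage failure is re-raised annotated with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {
        "package": "trabqtl",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": _config_hash(config),
    }
    outputs: dict[str, str] = {}
    stage = "configure"
    try:
        stage = "simulate" if config.simulate else "load"
        if config.simulate:
            panel = simulate_consomic_panel(PanelSpec(seed=config.seed))
            gmap, sub = simulate_subconsomic_panel(
                SubconsomicSpec(seed=config.seed + 1)
            )
            write_phenotype_table(panel, out / "consomic_phenotypes.csv")
            write_phenotype_table(sub, out / "subconsomic_phenotypes.csv")
            write_genotype_map(gmap, out / "genotype_map.tsv")
            outputs["consomic_phenotypes"] = str(out / "consomic_phenotypes.csv")
            outputs["subconsomic_phenotypes"] = str(out / "subconsomic_phenotypes.csv")
            outputs["genotype_map"] = str(out / "genotype_map.tsv")
            control, donor = "B6", "MSM"
        else:
            panel = read_phenotype_table(config.phenotype_csv)
            sub = read_phenotype_table(config.sub_phenotype_csv)
            gmap = read_genotype_map(
                config.genotype_tsv, host=config.sub_host, donor=config.sub_donor
            )
            control, donor = config.control, config.donor
        log.info("panel: %d rows, %d strains", len(panel), panel["strain"].nunique())

        stage = "screen"
        screen = dunnett_screen(panel, control=control, donor=donor,
                                alpha=config.alpha_screen)
        screen.frame.to_csv(out / "screen_report.tsv", sep="\t", index=False)
        outputs["screen_report"] = str(out / "screen_report.tsv")
        corr = spearman_matrix(panel)
        corr.rho.to_csv(out / "correlation_rho.tsv", sep="\t")
        corr.p.to_csv(out / "correlation_p.tsv", sep="\t")
        outputs["correlation_rho"] = str(out / "correlation_rho.tsv")
        outputs["correlation_p"] = str(out / "correlation_p.tsv")
        summary = {
            "nonadditivity_percent": {},
            "strain_order": {},
        }
        for param in screen.frame["parameter"].unique():
            try:
                summary["nonadditivity_percent"][param] = nonadditivity_index(
                    screen, param
                )
            except ValueError:
                summary["nonadditivity_percent"][param] = None
            summary["strain_order"][param] = order_strains(screen, param)
        _dump_json(summary, out / "screen_summary.json", stamp)
        outputs["screen_summary"] = str(out / "screen_summary.json")

        stage = "map-blocks"
        order = order_by_similarity(gmap)
        partition = partition_blocks(gmap)
        report = neighbor_tests(
            order, sub, parameters=config.map_parameters,
            alpha_family=config.alpha_family,
        )
        report.frame.to_csv(out / "neighbor_report.tsv", sep="\t", index=False)
        outputs["neighbor_report"] = str(out / "neighbor_report.tsv")
        calls = assign_qtl(report, partition, gmap)
        _dump_json(
            {
                "strain_order": list(order),
                "blocks": {
                    name: list(iv)
                    for name, iv in zip(partition.names, partition.blocks)
                },
                "threshold": report.threshold,
                "qtl_calls": [
                    {
                        "blocks": list(c.blocks),
                        "intervals": [list(iv) for iv in c.intervals],
                        "parameter": c.parameter,
                        "direction": c.direction,
                        "pair": list(c.pair),
                        "p": c.p,
                        "ambiguous": c.ambiguous,
                    }
                    for c in calls
                ],
            },
            out / "qtl_calls.json",
            stamp,
        )
        outputs["qtl_calls"] = str(out / "qtl_calls.json")

        stage = "provenance"
        _dump_json({"outputs": outputs}, out / "provenance.json", stamp)
        outputs["provenance"] = str(out / "provenance.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outputs
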