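"""End-to-end orchestration: read/simulate -> mask -> tree -> diversity ->
founder dating -> kriged surfaces -> radiocarbon comparison.

Every stage writes its artifact to the output directory so runs are
auditable and independently re-runnable; outputs are pure functions of
(inputs, config, seed) and byte-identical across reruns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import archaeo, diversity, founder as founder_mod, geospatial, network
from .clock import get_calibration
from .haplotype_io import (
    MitoHaplotype,
    PositionConfig,
    apply_position_mask,
    read_dataset,
    write_metadata,
    write_variant_table,
)
from .simulate import default_founder_config

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    seq_path: str | None = None
    meta_path: str | None = None
    position_cfg: PositionConfig = field(default_factory=PositionConfig.default)
    founder_cfg: object | None = None  # FounderConfig; defaults to packaged areas
    clock: str = "selection-corrected"
    grid_resolution: float = 0.5
    out_dir: str = "mtfounder-out"
    seed: int = 0
    min_n: int = 15
    tree_method: str = "auto"
    source_presence: str = "clade"


def _checked(stage: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - stage-named diagnostics
                raise PipelineError(stage, exc) from exc
        return wrapper
    return deco


def run_all(
    cfg: RunConfig,
    dataset: Sequence[MitoHaplotype] | None = None,
) -> dict:
    """Run every stage; returns a dict of artifact paths and key results."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    founder_cfg = cfg.founder_cfg or default_founder_config()
    cal = get_calibration(cfg.clock)

    if dataset is None:
        if not (cfg.seq_path and cfg.meta_path):
            raise PipelineError(
                "input", FileNotFoundError("seq_path and meta_path are required")
            )
        for p in (cfg.seq_path, cfg.meta_path):
            if not Path(p).exists():
                raise PipelineError("input", FileNotFoundError(p))
        dataset = _checked("read")(read_dataset)(cfg.seq_path, cfg.meta_path)

    masked = [apply_position_mask(h, cfg.position_cfg) for h in dataset]

    tree = _checked("network")(network.build_tree)(
        masked, cfg.position_cfg, method=cfg.tree_method
    )
    (out / "tree.nwk").write_text(network.export_newick(tree))
    (out / "tree_edges.tsv").write_text(network.export_edge_list(tree))

    div = _checked("diversity")(diversity.regional_diversity_table)(
        tree, masked, min_n=cfg.min_n
    )
    div.to_csv(out / "diversity.csv", index=False)

    results = _checked("founder")(founder_mod.run_founder_analysis)(
        tree, masked, founder_cfg, cal,
        source_presence=cfg.source_presence, min_n=cfg.min_n,
    )
    ftab = founder_mod.founder_table(results)
    ftab.to_csv(out / "founder.csv", index=False)

    surfaces = _checked("krige")(_surfaces)(
        masked, div, ftab, founder_cfg, cfg.grid_resolution, out
    )

    comparison = _checked("compare")(_compare)(ftab, out)

    meta = {"seed": cfg.seed, "clock": cal.id, "n_samples": len(dataset)}
    (out / "run_meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    return {
        "tree": tree,
        "diversity": div,
        "founder": ftab,
        "founder_results": results,
        "surfaces": surfaces,
        "comparison": comparison,
        "out_dir": str(out),
    }


def _surfaces(masked, div, ftab, founder_cfg, resolution, out: Path):
    coords: dict[str, tuple[float, float]] = {}
    for h in masked:
        coords.setdefault(h.region, (h.lat, h.lon))

    made = {}
    for stat, table, col in (
        ("pi", div, "pi"),
        ("rho", div, "rho"),
        ("age", ftab, "age_bp"),
    ):
        points = [
            geospatial.GeoPoint(r.region, *coords[r.region], float(getattr(r, col)))
            for r in table.itertuples()
            if r.region in coords
        ]
        points = geospatial.exclude_outliers(points, founder_cfg.exclusions)
        if not points:
            continue
        lo = min(p.lon for p in points) - 2
        hi = max(p.lon for p in points) + 2
        la0 = min(p.lat for p in points) - 2
        la1 = max(p.lat for p in points) + 2
        surf = geospatial.krige(points, (lo, hi, la0, la1, resolution))
        surf.to_csv(out / f"surface_{stat}.csv")
        surf.to_surfer_grd(out / f"surface_{stat}.grd")
        made[stat] = surf
    return made


def _compare(ftab: pd.DataFrame, out: Path):
    packaged = archaeo.load_packaged_table()
    c14 = packaged[packaged.c14_older.notna()]
    rows = []
    for r in ftab.itertuples():
        matches = c14[c14.region == r.region]
        if matches.empty:
            continue
        ranges = [
            (float(m.c14_older), float(m.c14_younger)) for m in matches.itertuples()
        ]
        overlap = any(
            archaeo.interval_overlap((float(r.ci_lo), float(r.ci_hi)), rng)
            for rng in ranges
        )
        rows.append(
            {
                "region": r.region,
                "age_bp": r.age_bp,
                "ci_lo": r.ci_lo,
                "ci_hi": r.ci_hi,
                "c14_older": max(x[0] for x in ranges),
                "c14_younger": min(x[1] for x in ranges),
                "overlap": overlap,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["region", "age_bp", "ci_lo", "ci_hi", "c14_older", "c14_younger", "overlap"],
    )
    df.to_csv(out / "comparison.csv", index=False)
    return df


def write_dataset(dataset: Sequence[MitoHaplotype], out_dir) -> tuple[Path, Path]:
    """Write a dataset in the formats the reader accepts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seq = out / "haplotypes.tsv"
    meta = out / "metadata.csv"
    write_variant_table(dataset, seq)
    write_metadata(dataset, meta)
    return seq, meta
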