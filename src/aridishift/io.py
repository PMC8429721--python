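"""Tabular I/O, pipeline configuration, and the end-to-end runner."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import indices, mixed, synthetic, thresholds, window

__all__ = ["PipelineConfig", "SchemaError", "read_site_table", "run_pipeline"]

log = logging.getLogger("aridishift")

#: Mandatory columns of a site table.
SITE_SCHEMA = (
    "site_id",
    "aridity",
    "year",
    "soil_type",
    "vegetation_type",
    "soil_pH",
    "clay",
    "plant_richness",
    "archaeal_richness",
    "bacterial_richness",
    "fungal_richness",
    "ndvi",
    "agb",
    "root_biomass",
) + synthetic.FUNCTION_COLUMNS

NUMERIC_SITE_COLUMNS = tuple(
    c for c in SITE_SCHEMA if c not in ("site_id", "soil_type", "vegetation_type")
)


class SchemaError(ValueError):
    """A site table does not match the expected schema."""


def read_site_table(path: str | Path, schema=SITE_SCHEMA) -> pd.DataFrame:
    """Read a site table from CSV or TSV, validating the schema.

    The delimiter is auto-detected between comma and tab; a JSON sidecar
    (``<file>.meta.json``) with units/config metadata is loaded when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    head = path.open().readline()
    sep = "\t" if head.count("\t") > head.count(",") else ","
    table = pd.read_csv(path, sep=sep)
    missing = [c for c in schema if c not in table.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    for col in NUMERIC_SITE_COLUMNS:
        if col not in table.columns:
            continue
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"non-numeric value in numeric column {col!r} at row {row}"
            )
        table[col] = coerced
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        table.attrs.update(json.loads(sidecar.read_text()))
    log.info(
        "read %d sites from %s (%d NA cells)",
        len(table), path, int(table.isna().sum().sum()),
    )
    return table


@dataclass
class PipelineConfig:
    """Configuration of the one-command analysis pipeline."""

    input_path: str | None = None  # None -> generate synthetic data
    generator: synthetic.GeneratorConfig = field(
        default_factory=synthetic.GeneratorConfig
    )
    mf_variant: str = "full7"
    c: float = 0.80
    w: int = 60
    B: int = 500
    seed: int = 0
    output_dir: str = "aridishift_output"

    def resolved(self) -> dict:
        d = {
            "input_path": self.input_path,
            "mf_variant": self.mf_variant,
            "c": self.c,
            "w": self.w,
            "B": self.B,
            "seed": self.seed,
            "output_dir": self.output_dir,
            "generator": synthetic.config_to_dict(self.generator),
        }
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.resolved(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run indices -> per-function thresholds -> mixed models -> moving window
    -> region split, writing tidy reports and a machine-readable manifest.

    Every random stage derives its stream from ``config.seed`` through a
    spawned seed sequence, so identical configs give identical outputs.
    """
    if config.B < 100:
        log.warning("bootstrap B=%d is below the recommended minimum of 100",
                    config.B)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.resolved(),
        "config_hash": config.config_hash(),
        "stages": {},
    }
    bundle: dict = {"manifest": manifest}
    seed_root = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("thresholds", "moving_window"), seed_root.spawn(2)
        )
    }

    def stage(name, fn):
        try:
            bundle[name] = fn()
            manifest["stages"][name] = "ok"
        except Exception as exc:  # recorded, then re-raised by caller policy
            manifest["stages"][name] = f"failed: {exc}"
            (outdir / "manifest.json").write_text(
                json.dumps(manifest, indent=1, default=str)
            )
            raise RuntimeError(f"pipeline stage {name!r} failed") from exc

    def _load():
        if config.input_path:
            return read_site_table(config.input_path)
        gen = config.generator
        if gen.seed != config.seed:
            gen = synthetic.config_from_dict(
                {**synthetic.config_to_dict(gen), "seed": config.seed}
            )
        table = synthetic.generate_sites(gen)
        synthetic.write_table(table, outdir / "sites.csv")
        return table

    stage("load", _load)
    table = bundle["load"]

    def _indices():
        mf = indices.multifunctionality(table, config.mf_variant)
        matrix = indices.FunctionMatrix.from_table(
            table, mf.included_functions
        )
        mt = indices.multiple_threshold_analysis(
            indices.microbial_diversity_index(table), matrix
        )
        trade = indices.tradeoff_screen(matrix)
        trade.pairs.to_csv(outdir / "tradeoff_pairs.csv", index=False)
        (outdir / "multiple_threshold_summary.json").write_text(
            json.dumps(mt.summary(), indent=1, default=str)
        )
        return {"mf": mf, "mt": mt, "tradeoff": trade}

    stage("indices", _indices)
    prepared = mixed.prepare_analysis_table(table, config.mf_variant)

    def _thresholds():
        out = {}
        records = []
        for j, col in enumerate(
            list(synthetic.FUNCTION_COLUMNS) + ["multifunctionality"]
        ):
            y = (
                np.log10(prepared[col].to_numpy(float))
                if col != "multifunctionality"
                else prepared[col].to_numpy(float)
            )
            dec = thresholds.detect_threshold(
                prepared["aridity"].to_numpy(float), y,
                B=config.B, seed=stage_seeds["thresholds"] + j,
            )
            out[col] = dec
            records.append({"response": col, **dec.to_record()})
        pd.DataFrame(records).to_csv(
            outdir / "function_thresholds.csv", index=False
        )
        return out

    stage("thresholds", _thresholds)

    def _mixed():
        reports = {}
        for variant in ("full", "simplified"):
            spec = mixed.ModelSpec(variant=variant, c=config.c)
            design = mixed.build_design(prepared, spec)
            rep = mixed.fit_mixed(design)
            rep.table.to_csv(outdir / f"mixed_{variant}.csv", index=False)
            reports[variant] = rep
        return reports

    stage("mixed", _mixed)

    def _moving_window():
        res = window.moving_window_analysis(
            table, w=config.w, B=config.B,
            seed=stage_seeds["moving_window"],
        )
        res["long_frame"].to_csv(outdir / "trajectories.csv", index=False)
        decisions = {
            term: (traj.decision.to_record() if traj.decision else None)
            for term, traj in res["trajectories"].items()
        }
        (outdir / "trajectory_thresholds.json").write_text(
            json.dumps(decisions, indent=1, default=str)
        )
        return res

    stage("moving_window", _moving_window)

    def _region_split():
        rep = mixed.ols_by_region(prepared, c=config.c)
        rep.to_csv(outdir / "region_ols.csv", index=False)
        return rep

    stage("region_split", _region_split)

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, default=str)
    )
    return bundle
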