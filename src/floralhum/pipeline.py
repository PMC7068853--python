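"""Stage orchestration: probe log -> calibration -> dRH -> QC -> models
-> summaries (-> comparative fit), with tabular interchange formats.

Each stage is independently callable; :func:`run_pipeline` wires them
in survey order and stamps every bundle with the config hash and seed
so reruns are verifiable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration as cal
from . import io as fio
from . import models, phylo, qc, summaries
from .calibration import DeltaRHRecord


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated run parameters; unknown keys are rejected at load."""

    probe_log: str | None = None
    output_dir: str = "floralhum_out"
    pairing_tolerance: float | None = None
    delta_aic_threshold: float = 2.0
    bootstrap_n: int = 100
    turbulence_convention: str = "absolute"
    calibration_direction: str = "background_on_focal"
    seed: int = 0
    tree: str | None = None
    traits: str | None = None
    log_level: str = "INFO"
    species_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.delta_aic_threshold <= 0:
            raise ConfigError("delta_aic_threshold must be positive")
        if self.bootstrap_n <= 0:
            raise ConfigError("bootstrap_n must be positive")
        if self.pairing_tolerance is not None and self.pairing_tolerance <= 0:
            raise ConfigError("pairing_tolerance must be positive")
        if self.turbulence_convention not in ("absolute", "squared"):
            raise ConfigError(
                f"unknown turbulence convention {self.turbulence_convention!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must hold a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def calibration_frame(fits: dict) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"day": f.day_id, "replicate": f.replicate, "W": f.W, "M": f.M,
             "n": f.n_points, "r_squared": f.r_squared}
            for f in fits.values()
        ]
    )


def records_to_frame(records: list[DeltaRHRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"flower": r.flower_id, "species": r.species_id,
             "replicate": r.replicate, "axis": r.axis, "offset_mm": r.offset,
             "delta_rh": r.delta_rh, "within_period_sd": r.within_period_sd,
             "n_readings": r.n_readings}
            for r in records
        ]
    )


def frame_to_records(df: pd.DataFrame) -> list[DeltaRHRecord]:
    return [
        DeltaRHRecord(
            flower_id=str(row.flower),
            species_id=str(row.species),
            replicate=int(row.replicate),
            axis=str(row.axis),
            offset=float(row.offset_mm),
            delta_rh=float(row.delta_rh),
            within_period_sd=float(row.within_period_sd),
            n_readings=int(row.n_readings),
        )
        for row in df.itertuples()
    ]


def summarize_species(
    records: list[DeltaRHRecord],
    metadata: dict | None = None,
    delta_aic_threshold: float = 2.0,
) -> tuple[fio.SpeciesSummaryRow, models.SelectionResult, models.SelectionResult]:
    """Full per-species summary: select both axes, locate the peak."""
    sel_x, sel_z = models.fit_both_axes(records, delta_aic_threshold)
    peak = summaries.delta_rh_max(sel_x.chosen_fit)
    row = summaries.assemble_species_summary(sel_x, sel_z, peak, metadata or {})
    return row, sel_x, sel_z


def run_pipeline(config: RunConfig) -> dict:
    """Execute calibrate -> dRH -> QC -> fit/select -> summarize (-> pgls).

    Writes the output bundle under ``config.output_dir`` and returns a
    manifest dict. Any stage failure raises with the stage name.
    """
    if config.probe_log is None:
        raise ConfigError("run_pipeline requires probe_log")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.hash(), "seed": config.seed,
                      "stages": {}}

    def stage(name):
        def wrap(fn):
            try:
                result = fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = result
            return result

        return wrap

    periods = fio.read_probe_log(config.probe_log)

    @stage("calibrate")
    def _calibrate():
        fits = cal.fit_all_calibrations(
            periods, config.pairing_tolerance, config.calibration_direction
        )
        calibration_frame(fits).to_csv(out / "calibration.csv", index=False)
        return {"n_fits": len(fits)}

    fits = cal.fit_all_calibrations(
        periods, config.pairing_tolerance, config.calibration_direction
    )

    @stage("delta_rh")
    def _delta():
        records = cal.delta_rh_records(periods, fits, config.pairing_tolerance)
        records_to_frame(records).to_csv(out / "delta_rh.csv", index=False)
        return {"n_records": len(records)}

    records = cal.delta_rh_records(periods, fits, config.pairing_tolerance)

    @stage("qc")
    def _qc():
        turb = []
        for p in periods:
            if p.is_usable:
                turb.append(qc.turbulence_change(
                    p, convention=config.turbulence_convention))
        reg = qc.turbulence_regression(turb)
        values, labels = [], []
        for p in periods:
            if p.axis == "probe_control" or not p.is_usable:
                continue
            diffs = cal.paired_differences(
                p, fits[(p.day_id, p.replicate)], config.pairing_tolerance
            )
            values.extend(diffs.tolist())
            labels.extend([str(p.key)] * len(diffs))
        rep = qc.repeatability(values, labels, config.bootstrap_n, config.seed)
        pd.DataFrame([vars(t) for t in turb]).to_csv(
            out / "turbulence.csv", index=False
        )
        report = {
            "repeatability": vars(rep),
            "turbulence_regression": {
                "params": reg.params, "bse": reg.bse, "t": reg.tvalues,
                "p": reg.pvalues, "n": reg.n,
            },
        }
        (out / "qc.json").write_text(json.dumps(report, indent=2))
        return {"repeatability_R": rep.R}

    @stage("summarize")
    def _summarize():
        rows = []
        for species in sorted({r.species_id for r in records}):
            recs = [r for r in records if r.species_id == species]
            meta = dict(config.species_metadata.get(species, {}))
            meta.setdefault("name", species)
            row, sel_x, sel_z = summarize_species(
                recs, meta, config.delta_aic_threshold
            )
            models.aic_table_frame(sel_x).to_csv(
                out / f"aic_{species}_x.csv", index=False
            )
            models.aic_table_frame(sel_z).to_csv(
                out / f"aic_{species}_z.csv", index=False
            )
            rows.append(row)
        summaries.assign_ranks(rows)
        fio.write_summary_table(rows, out / "summary.csv")
        return {"n_rows": len(rows)}

    if config.tree and config.traits:
        @stage("pgls")
        def _pgls():
            tree = phylo.load_tree(config.tree)
            traits = phylo.prepare_traits(pd.read_csv(config.traits))
            bm = phylo.pgls_fit(traits, tree, "BM")
            ou = phylo.pgls_fit(traits, tree, "OU", estimate_alpha=True)
            best = ou if ou.aic <= bm.aic else bm
            null = phylo.pgls_fit(
                traits, tree, best.correlation_model,
                alpha=best.alpha, predictors=()
            )
            cmp_corr = phylo.compare_models(ou, bm, nested=True)
            cmp_null = phylo.compare_models(best, null, nested=True)
            best.effect_table().to_csv(out / "pgls_effects.csv", index=False)
            report = {
                "bm_aic": bm.aic, "ou_aic": ou.aic,
                "ou_alpha": ou.alpha,
                "chosen": best.correlation_model,
                "ou_vs_bm": vars(cmp_corr),
                "full_vs_null": vars(cmp_null),
            }
            (out / "pgls.json").write_text(json.dumps(report, indent=2))
            return {"chosen": best.correlation_model}

    manifest_json = json.dumps(manifest, indent=2, default=float)
    (out / "manifest.json").write_text(manifest_json)
    return manifest
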