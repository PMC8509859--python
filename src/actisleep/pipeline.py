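"""End-to-end orchestration: ingest -> features -> cohort -> PRS -> battery.

Every scalar tuning constant of the analysis lives in :class:`RunConfig`
with its standard default (30-min anchors, 60-min gaps, 3 PM day start, 10%
imputation cut, 2-day validity floor, noon afternoon cut, p < 0.05 PRS
threshold, r^2 <= 0.2 within 500 kb, 5% FDR).  A run writes its effective
settings next to its outputs, logs per-stage participant-flow counts, and
is deterministic for fixed inputs and config.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import battery as battery_mod
from . import cohort as cohort_mod
from . import features as features_mod
from . import hypnogram as hyp
from . import prs as prs_mod

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Input paths and analysis thresholds for one pipeline run."""

    bouts: Path
    participants: Path
    diagnoses: Path | None = None
    sumstats: list[Path] = Field(default_factory=list)
    genotypes: Path | None = None
    outdir: Path = Path("actisleep_results")

    bout_dialect: str = "bout"
    epoch_minutes: float | None = None
    imputed_threshold: float = 0.5
    anchor_minutes: float = 30.0
    gap_minutes: float = 60.0
    imputed_max_fraction: float = 0.10
    min_valid_days: int = 2
    afternoon_wakeup_h: float = 36.0   # noon, in hours since reference midnight
    variability: str = "median"
    p_cut: float = 0.05
    r2_max: float = 0.2
    window_bp: int = 500_000
    fdr_q: float = 0.05
    fdr_family: str = "battery"
    min_n: int = 30
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


def _load_participants(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    df["accel_start"] = pd.to_datetime(df["accel_start"]).dt.date
    df["season"] = df["accel_start"].map(battery_mod.season_of)
    return df.set_index("participant_id")


def compute_features_stage(cfg: RunConfig):
    """Ingest bouts and derive per-day and per-participant sleep measures."""
    recordings, rejected = hyp.read_bout_table(
        cfg.bouts, dialect=cfg.bout_dialect, epoch_minutes=cfg.epoch_minutes
    )
    recordings = [
        hyp.normalize(hyp.resolve_imputed(r, cfg.imputed_threshold)) for r in recordings
    ]
    per_day, per_participant, attrition = features_mod.compute_sleep_measures(
        recordings,
        min_valid_days=cfg.min_valid_days,
        variability=cfg.variability,
        anchor_minutes=cfg.anchor_minutes,
        gap_minutes=cfg.gap_minutes,
        imputed_max_fraction=cfg.imputed_max_fraction,
        afternoon_wakeup_h=cfg.afternoon_wakeup_h,
    )
    flow = {
        "participants_in": len(recordings) + len(rejected),
        "rejected_invalid_intervals": len(rejected),
        **{
            f"excluded_{row.reason}": int(row.n)
            for row in attrition.itertuples()
            if row.reason != "none"
        },
        "participants_out": len(per_participant),
    }
    return per_day, per_participant, flow


def run(cfg: RunConfig) -> dict[str, Path]:
    """Execute all stages, writing CSV outputs plus an attrition log.

    The PRS stage is skipped with a notice when genotypes or summary
    statistics are not configured; the diagnosis battery is skipped when no
    diagnosis file is given.  Returns the paths of everything written.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "effective_config.yaml").write_text(
        yaml.safe_dump(json.loads(cfg.model_dump_json()), sort_keys=True)
    )
    attrition_log: dict[str, dict] = {}

    participants = _load_participants(cfg.participants)
    per_day, per_participant, flow = compute_features_stage(cfg)
    attrition_log["features"] = flow
    per_day.to_csv(outdir / "per_day.csv", index=False)
    per_participant.to_csv(outdir / "measures.csv", index=False)

    measured = per_participant.set_index("participant_id")
    measures = measured[features_mod.MEASURE_NAMES]
    covars = participants.loc[measures.index.intersection(participants.index)]
    measures = measures.loc[covars.index]

    exposures = pd.DataFrame(index=measures.index)
    if cfg.diagnoses is not None:
        diag = pd.read_csv(
            cfg.diagnoses, dtype={"participant_id": str}, keep_default_na=False
        )
        assignments = cohort_mod.build_cohort(
            diag, participants["accel_start"]
        )
        assignments.to_csv(outdir / "assignments.csv", index=False)
        expo = cohort_mod.exposure_matrix(assignments)
        expo = expo.reindex(measures.index)
        exposures = pd.concat([exposures, expo], axis=1)
        attrition_log["cohort"] = {
            d: {
                k: int(v)
                for k, v in assignments[assignments["disorder"] == d]["status"]
                .value_counts()
                .items()
            }
            for d in assignments["disorder"].unique()
        }
    else:
        logger.info("no diagnosis file configured; diagnosis battery skipped")

    if cfg.genotypes is not None and cfg.sumstats:
        geno = prs_mod.read_dosage_matrix(cfg.genotypes)
        for ss_path in cfg.sumstats:
            name = Path(ss_path).stem
            sumstats = pd.read_csv(ss_path, sep="\t")
            scores, model = prs_mod.build_prs(
                sumstats, geno, p_cut=cfg.p_cut, r2_max=cfg.r2_max,
                window_bp=cfg.window_bp,
            )
            model.variants.to_csv(outdir / f"prs_model_{name}.tsv", sep="\t", index=False)
            scores.rename(f"prs_{name}").to_csv(outdir / f"prs_scores_{name}.csv")
            exposures[f"prs_{name}"] = scores.reindex(measures.index)
            attrition_log[f"prs_{name}"] = model.provenance
    else:
        logger.info("genotypes or summary statistics not configured; PRS stage skipped")

    outputs = {
        "per_day": outdir / "per_day.csv",
        "measures": outdir / "measures.csv",
        "attrition": outdir / "attrition.json",
        "config": outdir / "effective_config.yaml",
    }
    if not exposures.empty:
        results = battery_mod.run_battery(
            measures, exposures, covars, q=cfg.fdr_q, family=cfg.fdr_family,
            min_n=cfg.min_n,
        )
        results.to_csv(outdir / "associations.csv", index=False)
        outputs["associations"] = outdir / "associations.csv"

    # attrition conservation: in == out + excluded, asserted before writing
    f = attrition_log["features"]
    dropped = sum(v for k, v in f.items() if k.startswith(("rejected_", "excluded_")))
    assert f["participants_in"] == f["participants_out"] + dropped
    (outdir / "attrition.json").write_text(json.dumps(attrition_log, indent=2))
    return outputs
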