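"""Synthetic cohort generation: hypnograms, diagnoses, genotypes, GWAS panels.

The generator gives every pipeline stage a self-contained test surface.  It
operates at two levels:

* :func:`generate` writes a full on-disk bundle — week-long bout-level
  hypnograms with circadian structure, a participant table, diagnosis
  records with contamination (primary-care/death/self-report and
  post-accelerometry inpatient records), genotypes with a planted additive
  liability, and GWAS summary statistics simulated on an *independent*
  panel, so that PRS construction is evaluated honestly.

* :func:`simulate_association_cohort` is a measure-level simulator that
  draws the 10 participant-level sleep measures directly from the latent
  model with planted standardized effects, making the association battery's
  estimand exactly the planted value.  It is the tool for calibration
  studies (type-I error, parameter recovery, CI coverage) where rendering
  bouts would only add noise between the truth and the estimand.

Population parameters default to values typical of community cohorts
(median bedtime ≈ 23:20, median sleep duration ≈ 7.9 h, one awakening per
night, most days nap-free).  Hypnograms are rendered on a one-minute grid,
so all durations are whole minutes and conservation identities hold exactly.
"""

from __future__ import annotations

import json
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .cohort import ANY_DIAGNOSIS, DISORDERS
from .hypnogram import Bout, Recording, State

MINUTES_PER_DAY = 1440
REC_START_HOUR = 10  # recordings begin at 10:00 on the accelerometry start date


class GeneratorConfig(BaseModel):
    """Population and planted-effect parameters for the synthetic cohort."""

    n_participants: int = 200
    n_days: int = 7
    seed: int = 0

    # circadian structure (hours unless noted)
    mean_bedtime_h: float = 23.3
    mean_sleep_duration_h: float = 7.9
    between_sd_bedtime_h: float = 1.0
    within_sd_bedtime_h: float = 0.5
    between_sd_duration_h: float = 0.8
    within_sd_duration_h: float = 0.6
    awakening_rate: float = 1.2        # Poisson mean awakenings per night
    nap_rate: float = 0.3              # per-day probability of a >30-min nap
    imputed_rate: float = 0.15         # per-day probability of a nonwear (imputed) block

    # diagnoses
    diagnosis_prevalences: dict[str, float] = Field(
        default_factory=lambda: {
            "major_depressive_disorder": 0.017,
            "anxiety": 0.0094,
            "bipolar_mania": 0.0014,
            "schizophrenia_spectrum": 0.0008,
        }
    )
    genetic_liability_rho: float = 0.3  # corr(liability, genetic score) for genetic disorders
    contamination_rate: float = 0.02    # non-cases with a non-inpatient record
    post_accel_rate: float = 0.005      # non-cases whose first inpatient record postdates accelerometry

    # genetics
    n_variants: int = 300
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 30
    prs_effect_size: float = 0.15      # SD of causal per-variant effects (standardized dosage scale)
    n_gwas: int = 4000                 # independent GWAS panel size
    missing_rate: float = 0.02         # genotype missingness in the cohort

    # planted standardized effects: exposure -> measure -> beta.
    # The bout renderer honors bedtime, sleep_duration and n_naps entries;
    # simulate_association_cohort honors every measure.
    effect_matrix: dict[str, dict[str, float]] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        for k, v in self.diagnosis_prevalences.items():
            if not 0.0 < v < 1.0:
                raise ValueError(f"prevalence for {k} out of (0,1): {v}")
        if self.mean_sleep_duration_h >= 12.0:
            raise ValueError("mean sleep duration must be below 12 h")
        if not 0.0 < self.maf_range[0] < self.maf_range[1] <= 0.5:
            raise ValueError(f"invalid maf_range: {self.maf_range}")
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal exceeds n_variants")
        return self


# ---------------------------------------------------------------------------
# hypnogram rendering (one-minute grid)


def _render_recording(
    rng: np.random.Generator,
    participant_id: str,
    accel_date: date,
    cfg: GeneratorConfig,
    bedtime_mean_h: float,
    duration_mean_h: float,
    nap_p: float,
) -> Recording:
    """Render one participant's recording on a minute grid and run-length encode it."""
    n_days = cfg.n_days
    total = n_days * MINUTES_PER_DAY + 8 * 60  # 10:00 day 0 .. 18:00 day n
    sleep = np.zeros(total, dtype=bool)
    imputed = np.zeros(total, dtype=bool)
    p_sleep = np.full(total, np.nan)
    origin = datetime.combine(accel_date, time(REC_START_HOUR, 0))

    for j in range(n_days):
        midnight = j * MINUTES_PER_DAY - REC_START_HOUR * 60
        bed_h = float(np.clip(bedtime_mean_h + rng.normal(0, cfg.within_sd_bedtime_h), 20.5, 27.0))
        dur_h = float(np.clip(duration_mean_h + rng.normal(0, cfg.within_sd_duration_h), 4.0, 11.0))
        onset = midnight + int(round(bed_h * 60))
        dur = int(round(dur_h * 60))

        n_awk = int(rng.poisson(cfg.awakening_rate))
        n_awk = max(0, min(n_awk, dur // 30 - 1))
        wake_lens = rng.integers(3, 13, n_awk) if n_awk else np.empty(0, dtype=int)
        extra = dur - 30 * (n_awk + 1)
        props = rng.dirichlet(np.ones(n_awk + 1)) if n_awk else np.ones(1)
        segs = 30 + np.floor(props * extra).astype(int)
        segs[0] += dur - int(segs.sum())
        pos = onset
        for k, seg in enumerate(segs):
            sleep[pos: pos + seg] = True
            pos += seg
            if k < n_awk:
                pos += int(wake_lens[k])

        if rng.random() < nap_p:
            nap_len = int(rng.integers(35, 81))
            nap_start = midnight + 16 * 60 + int(rng.integers(0, 90))
            if nap_start >= 0:
                sleep[nap_start: nap_start + nap_len] = True

        if rng.random() < cfg.imputed_rate:
            blk_len = int(rng.integers(20, 121))
            blk_start = midnight + 18 * 60 + int(rng.integers(0, 60))
            p = float(np.round(rng.uniform(0.05, 0.95), 3))
            imputed[blk_start: blk_start + blk_len] = True
            p_sleep[blk_start: blk_start + blk_len] = p
            sleep[blk_start: blk_start + blk_len] = p > 0.5

    # run-length encode (state, imputed) into bouts
    keys = sleep.astype(np.int8) * 2 + imputed.astype(np.int8)
    change = np.flatnonzero(np.diff(keys)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [total]])
    bouts = []
    for s, e in zip(starts, ends):
        bouts.append(
            Bout(
                start=origin + timedelta(minutes=int(s)),
                end=origin + timedelta(minutes=int(e)),
                state=State.SLEEP if sleep[s] else State.WAKE,
                imputed=bool(imputed[s]),
                p_sleep=float(p_sleep[s]) if imputed[s] else None,
            )
        )
    rec = Recording(participant_id, bouts)
    rec.validate()
    return rec


# ---------------------------------------------------------------------------
# genetics


def _simulate_dosages(
    rng: np.random.Generator, n: int, mafs: np.ndarray, ld_copy: np.ndarray
) -> np.ndarray:
    """participants x variants dosage matrix; every variant flagged in
    ``ld_copy`` is a noisy copy of its predecessor (planted LD)."""
    g = rng.binomial(2, mafs, size=(n, mafs.size)).astype(float)
    for j in np.flatnonzero(ld_copy):
        keep = rng.random(n) < 0.9
        g[:, j] = np.where(keep, g[:, j - 1], g[:, j])
    return g


def _marginal_gwas(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant marginal regression slopes and normal-theory p-values."""
    from scipy import stats

    n = g.shape[0]
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    var = (gc ** 2).sum(axis=0)
    var[var == 0] = np.nan
    beta = gc.T @ yc / var
    resid_var = ((yc ** 2).sum() - beta ** 2 * var) / (n - 2)
    se = np.sqrt(resid_var / var)
    z = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return beta, p


_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("C", "A"), ("G", "A")]


def _simulate_genetics(rng: np.random.Generator, n_cohort: int, cfg: GeneratorConfig):
    n_v = cfg.n_variants
    mafs = rng.uniform(*cfg.maf_range, n_v)
    half = n_v // 2
    chrom = np.where(np.arange(n_v) < half, "1", "2")
    pos = np.concatenate(
        [1_000_000 + 150_000 * np.arange(half),
         1_000_000 + 150_000 * np.arange(n_v - half)]
    )
    ld_copy = np.zeros(n_v, dtype=bool)
    ld_copy[5::10] = True  # every 10th variant shadows its neighbor
    ld_copy[[0, half]] = False
    mafs[ld_copy] = mafs[np.flatnonzero(ld_copy) - 1]

    causal = rng.choice(np.flatnonzero(~ld_copy), cfg.n_causal, replace=False)
    b = np.zeros(n_v)
    b[causal] = rng.normal(0, cfg.prs_effect_size, cfg.n_causal)

    g_cohort = _simulate_dosages(rng, n_cohort, mafs, ld_copy)
    g_panel = _simulate_dosages(rng, cfg.n_gwas, mafs, ld_copy)

    def liability(g):
        scale = np.sqrt(2 * mafs * (1 - mafs))
        gs = (g - 2 * mafs) / scale
        raw = gs @ b
        sd = raw.std()
        return raw / sd if sd > 0 else raw

    lia_cohort = liability(g_cohort)
    lia_panel = liability(g_panel) + rng.normal(0, 1.0, cfg.n_gwas)
    beta_hat, p_hat = _marginal_gwas(g_panel, lia_panel)

    ref = np.array([_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)][0] for i in range(n_v)])
    alt = np.array([_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)][1] for i in range(n_v)])
    variants = pd.DataFrame(
        {"id": [f"rs{i + 1}" for i in range(n_v)], "chrom": chrom, "pos": pos,
         "ref_allele": ref, "alt_allele": alt}
    )
    miss = rng.random(g_cohort.shape) < cfg.missing_rate
    g_cohort[miss] = np.nan

    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    eff, oth = alt.copy(), ref.copy()
    strand_flip = rng.random(n_v) < 0.1  # some sumstats reported on the other strand
    eff[strand_flip] = [comp[a] for a in eff[strand_flip]]
    oth[strand_flip] = [comp[a] for a in oth[strand_flip]]
    swap = rng.random(n_v) < 0.2  # some report the ref allele as effect allele
    eff[swap], oth[swap] = oth[swap].copy(), eff[swap].copy()
    beta_ss = np.where(swap, -beta_hat, beta_hat)
    ambiguous = rng.random(n_v) < 0.05  # a few A/T variants, dropped at harmonization
    eff[ambiguous] = "A"
    oth[ambiguous] = "T"
    sumstats = pd.DataFrame(
        {"id": variants["id"], "chrom": chrom, "pos": pos,
         "effect_allele": eff, "other_allele": oth,
         "beta": beta_ss, "p": p_hat}
    )
    truth = {
        "causal_variants": [f"rs{i + 1}" for i in sorted(causal)],
        "n_causal": int(cfg.n_causal),
        "ld_copies": int(ld_copy.sum()),
    }
    return variants, g_cohort, lia_cohort, sumstats, truth


# ---------------------------------------------------------------------------
# full bundle


def _standardized_shift(beta: float, x: np.ndarray) -> np.ndarray:
    """beta * z(x): the latent-mean shift that plants a standardized effect."""
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return beta * (x - x.mean()) / sd


def generate(config: GeneratorConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the full synthetic bundle and return the paths of its files.

    Files: ``bouts.csv`` (bout-dialect hypnograms), ``participants.csv``
    (demographics, PCs, accelerometry start), ``diagnoses.csv``,
    ``sumstats.tsv``, ``genotypes.csv`` (dosage matrix) and ``truth.json``
    (every planted parameter).  Output is byte-identical for a fixed config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(root)
    n = config.n_participants
    pids = [f"P{i + 1:05d}" for i in range(n)]

    # demographics
    age = np.round(rng.uniform(43, 79, n), 1)
    sex = (rng.random(n) < 0.56).astype(int)  # 1 = female
    townsend = np.round(rng.normal(0, 3, n), 3)
    pcs = np.round(rng.normal(0, 1, (n, 10)), 4)
    start0 = date(2013, 6, 1)
    accel_dates = [start0 + timedelta(days=int(d)) for d in rng.integers(0, 700, n)]

    # genetics and diagnosis liabilities
    variants, g_cohort, lia, sumstats, gen_truth = _simulate_genetics(rng, n, config)
    statuses: dict[str, np.ndarray] = {}
    for name in DISORDERS:
        prev = config.diagnosis_prevalences[name]
        rho = config.genetic_liability_rho if name != "anxiety" else 0.0
        z = rho * lia + np.sqrt(1 - rho ** 2) * rng.normal(0, 1, n)
        from scipy import stats as _st
        statuses[name] = (z > _st.norm.ppf(1 - prev)).astype(int)
    any_case = (np.column_stack(list(statuses.values())).sum(axis=1) > 0).astype(int)

    # person-level latent sleep parameters with planted effects
    bed_mean = config.mean_bedtime_h + rng.normal(0, config.between_sd_bedtime_h, n)
    dur_mean = config.mean_sleep_duration_h + rng.normal(0, config.between_sd_duration_h, n)
    nap_p = np.full(n, config.nap_rate)
    exposures_for_planting = {**statuses, ANY_DIAGNOSIS: any_case, "genetic_liability": lia}
    for exp_name, effects in config.effect_matrix.items():
        if exp_name not in exposures_for_planting:
            continue
        x = exposures_for_planting[exp_name]
        if "bedtime" in effects:
            bed_mean = bed_mean + _standardized_shift(
                effects["bedtime"] * config.between_sd_bedtime_h, x)
        if "sleep_duration" in effects:
            dur_mean = dur_mean + _standardized_shift(
                effects["sleep_duration"] * config.between_sd_duration_h, x)
        if "n_naps" in effects:
            nap_p = np.clip(nap_p + _standardized_shift(0.5 * effects["n_naps"], x), 0.0, 1.0)

    # hypnograms (per-participant substreams for reproducibility)
    substreams = root.spawn(n)
    recordings = [
        _render_recording(
            np.random.default_rng(substreams[i]), pids[i], accel_dates[i], config,
            float(bed_mean[i]), float(dur_mean[i]), float(nap_p[i]),
        )
        for i in range(n)
    ]

    # diagnosis records
    diag_rows = []
    for name in DISORDERS:
        prefixes = sorted(DISORDERS[name].icd_prefixes)
        case = statuses[name]
        for i in range(n):
            code = prefixes[int(rng.integers(0, len(prefixes)))]
            if case[i]:
                d = accel_dates[i] - timedelta(days=int(rng.integers(30, 3650)))
                diag_rows.append((pids[i], code, "inpatient", d.isoformat()))
            elif rng.random() < config.post_accel_rate:
                d = accel_dates[i] + timedelta(days=int(rng.integers(30, 1000)))
                diag_rows.append((pids[i], code, "inpatient", d.isoformat()))
            elif rng.random() < config.contamination_rate:
                src = ("primary_care", "death", "self_report")[int(rng.integers(0, 3))]
                d = "" if src == "self_report" else (
                    accel_dates[i] - timedelta(days=int(rng.integers(30, 3650)))
                ).isoformat()
                diag_rows.append((pids[i], code, src, d))
    diagnoses = pd.DataFrame(
        diag_rows, columns=["participant_id", "icd_code", "source", "date"]
    )

    # write bundle
    from .hypnogram import write_bout_table

    paths = {
        "bouts": outdir / "bouts.csv",
        "participants": outdir / "participants.csv",
        "diagnoses": outdir / "diagnoses.csv",
        "sumstats": outdir / "sumstats.tsv",
        "genotypes": outdir / "genotypes.csv",
        "truth": outdir / "truth.json",
    }
    write_bout_table(recordings, paths["bouts"])
    participants = pd.DataFrame(
        {"participant_id": pids, "age": age, "sex": sex, "townsend": townsend,
         "accel_start": [d.isoformat() for d in accel_dates],
         **{f"pc{k + 1}": pcs[:, k] for k in range(10)}}
    )
    participants.to_csv(paths["participants"], index=False)
    diagnoses.to_csv(paths["diagnoses"], index=False)
    sumstats.to_csv(paths["sumstats"], sep="\t", index=False)
    geno_out = pd.concat(
        [variants, pd.DataFrame(g_cohort.T, columns=pids, index=variants.index)],
        axis=1,
    )
    geno_out.to_csv(paths["genotypes"], index=False, float_format="%.6g")
    truth = {
        "config": json.loads(config.model_dump_json()),
        "genetics": gen_truth,
        "case_counts": {k: int(v.sum()) for k, v in statuses.items()},
        "any_diagnosis_cases": int(any_case.sum()),
    }
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return paths


# ---------------------------------------------------------------------------
# measure-level simulator (calibration studies)


DEFAULT_COVARIATE_R2 = 0.2  # outcome variance explained by covariates


def simulate_association_cohort(
    n: int,
    seed: int,
    effects: Mapping[tuple[str, str], float] | None = None,
    prevalences: Mapping[str, float] | None = None,
    n_prs: int = 3,
    covariate_r2: float = DEFAULT_COVARIATE_R2,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Draw participant-level measures, exposures and covariates directly.

    Outcomes are Gaussian with unit variance, built as planted standardized
    effects on z-scored exposures plus covariate contributions explaining
    ``covariate_r2`` of the variance plus independent noise, so the
    association battery's estimand equals the planted effect exactly.
    ``effects`` maps (exposure, measure) -> standardized beta.  Diagnosis
    exposures are Bernoulli at their configured prevalence with the
    composite exposure as their union; PRS exposures are standard normal.

    Returns ``(measures, exposures, covars, truth)`` indexed by participant.
    """
    from .features import MEASURE_NAMES
    from .battery import SEASONS

    effects = dict(effects or {})
    prevalences = dict(
        prevalences
        or {
            "major_depressive_disorder": 0.017,
            "anxiety": 0.0094,
            "bipolar_mania": 0.0014,
            "schizophrenia_spectrum": 0.0008,
        }
    )
    rng = np.random.default_rng(seed)
    pids = [f"S{i + 1:06d}" for i in range(n)]

    covars = pd.DataFrame(
        {
            "age": rng.uniform(43, 79, n),
            "sex": (rng.random(n) < 0.56).astype(float),
            "townsend": rng.normal(0, 3, n),
            "season": rng.choice(SEASONS, n),
            **{f"pc{k}": rng.normal(0, 1, n) for k in range(1, 11)},
        },
        index=pids,
    )

    exposures = pd.DataFrame(index=pids)
    for name, prev in prevalences.items():
        exposures[name] = (rng.random(n) < prev).astype(float)
    exposures[ANY_DIAGNOSIS] = (
        exposures[list(prevalences)].sum(axis=1) > 0
    ).astype(float)
    for k in range(1, n_prs + 1):
        exposures[f"prs_{k}"] = rng.normal(0, 1, n)

    # covariate contribution: loadings on z-scored age/sex/townsend, fixed R^2
    cz = np.column_stack(
        [
            (covars[c] - covars[c].mean()) / covars[c].std()
            for c in ("age", "sex", "townsend")
        ]
    )
    load = np.sqrt(covariate_r2 / 3.0)

    measures = pd.DataFrame(index=pids)
    for m in MEASURE_NAMES:
        y = cz @ np.full(3, load)
        beta_sq = 0.0
        for (exp_name, meas_name), beta in effects.items():
            if meas_name != m:
                continue
            x = exposures[exp_name].to_numpy()
            sd = x.std()
            if sd == 0:
                raise ValueError(f"cannot plant effect on constant exposure {exp_name}")
            y = y + beta * (x - x.mean()) / sd
            beta_sq += beta ** 2
        resid_var = 1.0 - covariate_r2 - beta_sq
        if resid_var <= 0:
            raise ValueError("planted effects and covariates exceed unit variance")
        y = y + rng.normal(0, np.sqrt(resid_var), n)
        measures[m] = y

    truth = {"effects": {f"{e}:{m}": b for (e, m), b in effects.items()},
             "prevalences": prevalences, "covariate_r2": covariate_r2}
    return measures, exposures, covars, truth


# ---------------------------------------------------------------------------
# worked hypnogram catalogue (hand-auditable unit fixtures)


def _day_recording(pid: str, segments: list[tuple[str, str, str]],
                   base: date = date(2014, 3, 3)) -> Recording:
    """Build a recording from (start, end, kind) clock strings.

    Times are ``"d HH:MM"`` with d the day offset from ``base``; kinds are
    ``"sleep"``, ``"wake"``, or ``"imputed:P"`` (imputed with p_sleep P,
    resolved by the >0.5 rule).  Gaps between segments are filled with wake.
    """
    def ts(spec: str) -> datetime:
        d, hm = spec.split(" ")
        h, m = hm.split(":")
        return datetime.combine(base + timedelta(days=int(d)), time(int(h), int(m)))

    parsed = sorted(
        (ts(s), ts(e), kind) for s, e, kind in segments
    )
    bouts: list[Bout] = []
    cursor = parsed[0][0]
    for s, e, kind in parsed:
        if e <= cursor:  # canvas marker swallowed by an earlier segment
            continue
        if s > cursor:
            bouts.append(Bout(cursor, s, State.WAKE))
        s = max(s, cursor)
        if kind.startswith("imputed:"):
            p = float(kind.split(":")[1])
            bouts.append(Bout(s, e, State.SLEEP if p > 0.5 else State.WAKE,
                              imputed=True, p_sleep=p))
        else:
            bouts.append(Bout(s, e, State(kind)))
        cursor = e
    rec = Recording(pid, bouts)
    rec.validate()
    return rec


def _catalogue() -> dict[str, tuple[Recording, dict]]:
    """Each case: (recording, expected) with hand-traced expectations.

    Recordings run 12:00 day 0 -> 16:00 day 1, giving one complete 3 PM day
    window opening on day 0.  Onset/offset expectations are hours since
    midnight of day 0 (the window-start date), so evening clock times land
    at 20-24 h and post-midnight times at 24-39 h.
    """

    def rec(pid, sleeps, extra=None):
        # canvas endpoint markers; _day_recording gap-fills with wake
        segs = list(sleeps) + (extra or [])
        segs.append(("0 12:00", "0 12:01", "wake"))
        segs.append(("1 15:59", "1 16:00", "wake"))
        return _day_recording(pid, segs)

    cases: dict[str, tuple[Recording, dict]] = {}

    # Two >=30-min anchors 40 min apart chain into one PSP; a 20-min sleep
    # bout just before the first anchor is not an anchor and stays outside.
    cases["two_anchor_merge"] = (
        rec("wx_two_anchor", [
            ("0 23:00", "0 23:20", "sleep"),
            ("0 23:30", "1 03:00", "sleep"),
            ("1 03:40", "1 07:10", "sleep"),
        ]),
        {
            "valid": True,
            "psp_onset_h": 23.5, "psp_offset_h": 31.0 + 1.0 / 6.0,  # 07:10 next day
            "sleep_min": 420.0, "waso_min": 40.0, "n_awakenings": 1,
            "longest_bout_min": 210.0, "n_naps": 0,
        },
    )

    # Single 8-hour sleep bout: trivial one-anchor PSP.
    cases["one_anchor"] = (
        rec("wx_one_anchor", [("0 23:00", "1 07:00", "sleep")]),
        {
            "valid": True,
            "psp_onset_h": 23.0, "psp_offset_h": 31.0,
            "sleep_min": 480.0, "waso_min": 0.0, "n_awakenings": 0,
            "longest_bout_min": 480.0, "n_naps": 0,
        },
    )

    # 61-minute gap between anchors: chains stay separate, longer span wins.
    cases["gap_61"] = (
        rec("wx_gap61", [
            ("0 22:00", "1 06:00", "sleep"),
            ("1 07:01", "1 08:01", "sleep"),
        ]),
        {
            "valid": True,
            "psp_onset_h": 22.0, "psp_offset_h": 30.0,
            "sleep_min": 480.0, "waso_min": 0.0, "n_awakenings": 0,
            "longest_bout_min": 480.0, "n_naps": 1,  # 60-min bout outside PSP
        },
    )

    # Only sub-30-minute sleep: day invalid, no qualifying sleep.
    cases["no_sleep"] = (
        rec("wx_no_sleep", [("0 23:00", "0 23:25", "sleep")]),
        {"valid": False, "invalid_reason": "no_qualifying_sleep"},
    )

    # The day's only sleep period straddles the 15:00 boundary: invalid.
    cases["boundary_crosser"] = (
        rec("wx_boundary", [("1 10:00", "1 16:30", "sleep")]),
        {"valid": False, "invalid_reason": "psp_crosses_boundary"},
    )

    # 150 imputed minutes = 10.4% of the day: invalid despite a clean night.
    cases["imputed_heavy"] = (
        rec("wx_imputed", [("0 23:00", "1 07:00", "sleep")],
            extra=[("0 17:00", "0 19:30", "imputed:0.1")]),
        {"valid": False, "invalid_reason": "imputed_gt_10pct",
         "imputed_fraction": 150.0 / 1440.0},
    )

    # A 45-minute afternoon nap counts; an exactly-30-minute one does not.
    cases["nap_day"] = (
        rec("wx_naps", [
            ("0 16:00", "0 16:30", "sleep"),   # exactly 30 min: not a nap
            ("0 17:30", "0 18:15", "sleep"),   # 45 min: one nap
            ("0 23:00", "1 07:00", "sleep"),
        ]),
        {
            "valid": True,
            "psp_onset_h": 23.0, "psp_offset_h": 31.0,
            "sleep_min": 480.0, "waso_min": 0.0, "n_awakenings": 0,
            "longest_bout_min": 480.0, "n_naps": 1,
        },
    )

    # Post-midnight bedtime: clock 01:00 is 25.0 h since reference midnight.
    cases["post_midnight_bed"] = (
        rec("wx_postmid", [("1 01:00", "1 08:30", "sleep")]),
        {
            "valid": True,
            "psp_onset_h": 25.0, "psp_offset_h": 32.5,
            "sleep_min": 450.0, "waso_min": 0.0, "n_awakenings": 0,
            "longest_bout_min": 450.0, "n_naps": 0,
        },
    )

    return cases


WORKED_CASES = tuple(_catalogue().keys())


def make_worked_hypnogram(case_id: str) -> tuple[Recording, dict]:
    """Return a deterministic, hand-auditable fixture recording and its
    expected primary-sleep-period measures / validity verdict.

    See :data:`WORKED_CASES` for the catalogue.
    """
    cases = _catalogue()
    if case_id not in cases:
        raise KeyError(f"unknown worked case {case_id!r}; known: {sorted(cases)}")
    return cases[case_id]


def make_filter_demo_cohort() -> tuple[list[Recording], dict]:
    """A 20-participant cohort with known day- and participant-level violations.

    16 clean sleepers (7 valid days each), one participant with a
    boundary-crossing sleep period on one day, one with a 10.4%-imputed day,
    one with a single valid day (excluded), and one habitual afternoon waker
    (excluded).  Returns the recordings plus the hand-computed expectation.
    """
    base = date(2014, 5, 5)

    def clean_week(pid: str, bed: str = "23:00", wake: str = "07:00") -> Recording:
        segs = [("0 12:00", "0 12:01", "wake"), ("7 14:59", "7 15:00", "wake")]
        for d in range(7):
            segs.append((f"{d} {bed}", f"{d + 1} {wake}", "sleep"))
        return _day_recording(pid, segs, base=base)

    recs = [clean_week(f"D{i:02d}") for i in range(1, 17)]

    # one boundary-crossing day (day 3's sleep runs 10:00 -> 16:30)
    segs = [("0 12:00", "0 12:01", "wake"), ("7 14:59", "7 15:00", "wake")]
    for d in range(7):
        if d == 3:
            segs.append((f"{d + 1} 10:00", f"{d + 1} 16:30", "sleep"))
        else:
            segs.append((f"{d} 23:00", f"{d + 1} 07:00", "sleep"))
    recs.append(_day_recording("D17", segs, base=base))

    # one day with 150 imputed minutes (10.4% > 10%)
    segs = [("0 12:00", "0 12:01", "wake"), ("7 14:59", "7 15:00", "wake")]
    for d in range(7):
        segs.append((f"{d} 23:00", f"{d + 1} 07:00", "sleep"))
    segs.append(("2 17:00", "2 19:30", "imputed:0.1"))
    recs.append(_day_recording("D18", segs, base=base))

    # only one valid day: short recording covering a single complete window
    segs = [("0 14:00", "0 14:01", "wake"), ("1 16:00", "1 16:01", "wake"),
            ("0 23:00", "1 07:00", "sleep")]
    recs.append(_day_recording("D19", segs, base=base))

    # afternoon waker: sleeps 05:00 -> 13:00 every day (median wake-up 37 h)
    segs = [("0 12:00", "0 12:01", "wake"), ("7 14:59", "7 15:00", "wake")]
    for d in range(7):
        segs.append((f"{d + 1} 05:00", f"{d + 1} 13:00", "sleep"))
    recs.append(_day_recording("D20", segs, base=base))

    expected = {
        "n_participants": 20,
        "n_emitted_vectors": 18,
        "excluded": {"D19": "lt_min_valid_days", "D20": "afternoon_waker"},
        "valid_days": {**{f"D{i:02d}": 7 for i in range(1, 17)},
                       "D17": 6, "D18": 6, "D19": 1, "D20": 7},
        "invalid_day_reasons": {
            "D17": {"psp_crosses_boundary": 1},
            "D18": {"imputed_gt_10pct": 1},
        },
    }
    return recs, expected
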