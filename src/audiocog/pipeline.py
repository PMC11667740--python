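"""End-to-end pipeline: generate → simulate → score → analyze → report.

One seeded, configurable run produces the cohort table, the trial-level and
participant-level CSVs, the tidy results CSV and a human-readable report
whose reliability block mirrors the published summary layout (measure,
in-person mean (SD), web mean (SD), r, ICC).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    MEASURES,
    CohortConfig,
    MeasureCalibration,
    SelectionModel,
    simulate_study,
    task_rng,
)
from .errors import InsufficientDataError, ValidationError
from .matching import MatchingConfig
from .staircase import StaircaseConfig
from .stats import (
    BootstrapDiffResult,
    Chi2Result,
    IccResult,
    PearsonResult,
    SteigerResult,
    bootstrap_corr_diff,
    chi_square_2x2,
    icc_two_way,
    partial_corr,
    pearson_with_ci,
    preprocess,
    steiger_dependent_corr,
)

__all__ = [
    "AnalysisConfig",
    "RunConfig",
    "ReliabilityReport",
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "save_config",
    "simulate_measures",
    "validate_and_load_measures",
    "analyze_measures",
    "run_pipeline",
    "replicate_summary",
    "render_report",
]

log = logging.getLogger("audiocog")

MEASURE_COLUMNS = list(MEASURES)
ID_COLUMNS = ["participant_id", "setting"]
COVARIATE_COLUMNS = ["age", "pta_hf"]
OPTIONAL_COLUMNS = ["cohort", "hearing_category"]
PRECISION_MEASURES = ("AUM_F", "AUM_A")


@dataclass(frozen=True)
class AnalysisConfig:
    bootstrap_B: int = 1000
    alpha: float = 0.05
    icc_kind: str = "agreement"
    ci_method: str = "fisher"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.bootstrap_B < 100:
            raise ValidationError("bootstrap_B must be >= 100")


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of a pipeline run; one top-level seed drives everything."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)
    matching: MatchingConfig = field(default_factory=MatchingConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    replicates: int = 1


# --------------------------------------------------------------------------
# config serialization (YAML round trip)

def config_to_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["cohort"]["latent_corr"] = np.asarray(config.cohort.latent_corr).tolist()
    return d


def config_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    cohort = dict(d.get("cohort", {}))
    if "latent_corr" in cohort:
        cohort["latent_corr"] = np.asarray(cohort["latent_corr"], dtype=float)
    if "measure_calibration" in cohort:
        cohort["measure_calibration"] = {
            k: v if isinstance(v, MeasureCalibration) else MeasureCalibration(**v)
            for k, v in cohort["measure_calibration"].items()
        }
    if "selection_model" in cohort and not isinstance(cohort["selection_model"], SelectionModel):
        cohort["selection_model"] = SelectionModel(**cohort["selection_model"])
    if "hearing_mix" in cohort:
        cohort["hearing_mix"] = dict(cohort["hearing_mix"])
    if "age_range" in cohort:
        cohort["age_range"] = tuple(cohort["age_range"])
    sc = dict(d.get("staircase", {}))
    mc = dict(d.get("matching", {}))
    for key in ("freq_range", "am_range"):
        if key in mc:
            mc[key] = tuple(mc[key])
    ac = dict(d.get("analysis", {}))
    return RunConfig(
        seed=int(d.get("seed", 0)),
        cohort=CohortConfig(**cohort),
        staircase=StaircaseConfig(**sc),
        matching=MatchingConfig(**mc),
        analysis=AnalysisConfig(**ac),
        replicates=int(d.get("replicates", 1)),
    )


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def load_config(path) -> RunConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


# --------------------------------------------------------------------------
# simulation

def simulate_measures(config: RunConfig, seed: int | None = None, collect_trials: bool = False):
    """Run the generative study once.

    Returns ``(cohort_df, measures_df, trials_df)``; ``trials_df`` is None
    unless requested.  ``seed`` overrides the config seed (used by replicate
    runs).
    """
    seed = config.seed if seed is None else seed
    cohort, rows, trials = simulate_study(
        config.cohort,
        seed,
        staircase_config=config.staircase,
        matching_config=config.matching,
        collect_trials=collect_trials,
    )
    cohort_df = pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in cohort],
            "cohort": [p.cohort for p in cohort],
            "age": [p.age for p in cohort],
            "pta_hf": [p.pta_hf if p.pta_hf is not None else np.nan for p in cohort],
            "hearing_category": [p.hearing_category for p in cohort],
            "hearing_aid_user": [p.hearing_aid_user for p in cohort],
            "web_returner": [bool(p.web_returner) for p in cohort],
        }
    )
    measures_df = pd.DataFrame(rows)
    trials_df = pd.DataFrame(trials) if collect_trials else None
    return cohort_df, measures_df, trials_df


def validate_and_load_measures(path) -> pd.DataFrame:
    """Load and validate a participant-level measures CSV (long format).

    Requires the header ``participant_id, setting, GMSI, DIN, SIB, AUM_F,
    AUM_A`` (plus optional age/pta_hf/cohort/hearing_category columns); every
    (participant, setting) pair must be unique, setting must be ``inperson``
    or ``web``, measure cells must be numeric or empty (missing — preserved,
    never imputed), and the precision measures must be strictly positive
    (they are log-transformed downstream).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path)
    required = ID_COLUMNS + MEASURE_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    known = set(required + COVARIATE_COLUMNS + OPTIONAL_COLUMNS)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise ValidationError(f"unknown columns: {unknown}")
    bad_setting = df.loc[~df["setting"].isin(["inperson", "web"])]
    if len(bad_setting):
        raise ValidationError(
            f"invalid setting values at rows {bad_setting.index.tolist()}"
        )
    dup = df.duplicated(subset=ID_COLUMNS, keep=False)
    if dup.any():
        offenders = df.loc[dup, "participant_id"].unique().tolist()
        raise ValidationError(f"duplicate (participant, setting) rows for {offenders}")
    numeric_cols = MEASURE_COLUMNS + [c for c in COVARIATE_COLUMNS if c in df.columns]
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            raise ValidationError(
                f"non-numeric values in {col!r} at rows {df.index[bad].tolist()}"
            )
        df[col] = coerced
    for col in PRECISION_MEASURES:
        bad = df[col].notna() & (df[col] <= 0)
        if bad.any():
            raise ValidationError(
                f"non-positive precision in {col!r} at rows {df.index[bad].tolist()}"
            )
    return df


# --------------------------------------------------------------------------
# analysis

@dataclass(frozen=True)
class ReliabilityRow:
    measure: str
    n: int
    mean_inperson: float
    sd_inperson: float
    mean_web: float
    sd_web: float
    pearson: PearsonResult
    icc: IccResult


@dataclass(frozen=True)
class AssociationRow:
    name: str
    setting: str
    pearson: PearsonResult
    partial_age: PearsonResult | None


@dataclass
class ReliabilityReport:
    reliability: list
    bootstrap_comparisons: dict
    steiger_vs_age: dict
    steiger_vs_pta: dict
    chi_square: dict
    associations: list

    def to_frame(self) -> pd.DataFrame:
        """Tidy results table: one row per statistic."""
        rows = []
        for rel in self.reliability:
            rows.append(
                dict(name=f"retest_r[{rel.measure}]", estimate=rel.pearson.r,
                     ci_low=rel.pearson.ci_low, ci_high=rel.pearson.ci_high,
                     statistic=np.nan, df=np.nan, p=rel.pearson.p_value,
                     n=rel.pearson.n, method=f"pearson/{rel.pearson.ci_method}")
            )
            rows.append(
                dict(name=f"icc[{rel.measure}]", estimate=rel.icc.icc,
                     ci_low=np.nan, ci_high=np.nan, statistic=np.nan, df=np.nan,
                     p=np.nan, n=rel.icc.n, method=f"icc/{rel.icc.kind}")
            )
        for name, b in self.bootstrap_comparisons.items():
            rows.append(
                dict(name=f"r_diff[{name}]", estimate=b.mean_diff, ci_low=b.ci_low,
                     ci_high=b.ci_high, statistic=np.nan, df=np.nan, p=np.nan,
                     n=b.n, method=f"bootstrap B={b.B}")
            )
        for label, d in (("age", self.steiger_vs_age), ("pta", self.steiger_vs_pta)):
            for m, s in d.items():
                rows.append(
                    dict(name=f"steiger_{label}[{m}]", estimate=s.r_jk - s.r_jh,
                         ci_low=np.nan, ci_high=np.nan, statistic=s.statistic,
                         df=s.df, p=s.p_value, n=s.n, method="williams-steiger")
                )
        for name, c in self.chi_square.items():
            rows.append(
                dict(name=f"chi2[{name}]", estimate=np.nan, ci_low=np.nan,
                     ci_high=np.nan, statistic=c.statistic, df=c.df, p=c.p_value,
                     n=np.nan, method="pearson-chi2")
            )
        for a in self.associations:
            rows.append(
                dict(name=f"assoc[{a.name}][{a.setting}]", estimate=a.pearson.r,
                     ci_low=a.pearson.ci_low, ci_high=a.pearson.ci_high,
                     statistic=np.nan, df=np.nan, p=a.pearson.p_value,
                     n=a.pearson.n, method="pearson")
            )
            if a.partial_age is not None:
                rows.append(
                    dict(name=f"assoc_age_controlled[{a.name}][{a.setting}]",
                         estimate=a.partial_age.r, ci_low=a.partial_age.ci_low,
                         ci_high=a.partial_age.ci_high, statistic=np.nan,
                         df=np.nan, p=a.partial_age.p_value, n=a.partial_age.n,
                         method="partial-pearson")
                )
        return pd.DataFrame(rows)


def _wide_measures(measures: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long measures table to one row per participant."""
    keep = [c for c in COVARIATE_COLUMNS + ["cohort"] if c in measures.columns]
    base = measures.sort_values("setting").groupby("participant_id")[keep].first()
    wide = measures.pivot(index="participant_id", columns="setting", values=MEASURE_COLUMNS)
    wide.columns = [f"{m}_{s}" for m, s in wide.columns]
    for m in MEASURES:
        for s in ("inperson", "web"):
            col = f"{m}_{s}"
            if col not in wide.columns:
                wide[col] = np.nan
    return base.join(wide).reset_index()


def analyze_measures(
    measures: pd.DataFrame, analysis: AnalysisConfig | None = None, rng=None
) -> ReliabilityReport:
    """Full reliability and association analysis of a long measures table.

    Memory precisions are log-transformed first; every statistic uses the
    complete cases available to it and reports that n.  ``rng`` drives the
    bootstrap resampling (and bootstrap CIs when selected).
    """
    analysis = analysis or AnalysisConfig()
    if rng is None:
        rng = np.random.default_rng(0)
    measures = preprocess(measures, log_columns=[c for c in PRECISION_MEASURES], z_columns=[])
    wide = _wide_measures(measures)

    reliability = []
    for m in MEASURES:
        x = wide[f"{m}_inperson"]
        y = wide[f"{m}_web"]
        pairs = pd.concat([x, y], axis=1).dropna()
        pr = pearson_with_ci(
            pairs.iloc[:, 0], pairs.iloc[:, 1], alpha=analysis.alpha,
            ci_method=analysis.ci_method, rng=rng,
        )
        icc = icc_two_way(pairs.to_numpy(), kind=analysis.icc_kind)
        reliability.append(
            ReliabilityRow(
                measure=m, n=len(pairs),
                mean_inperson=float(pairs.iloc[:, 0].mean()),
                sd_inperson=float(pairs.iloc[:, 0].std(ddof=1)),
                mean_web=float(pairs.iloc[:, 1].mean()),
                sd_web=float(pairs.iloc[:, 1].std(ddof=1)),
                pearson=pr, icc=icc,
            )
        )

    comparisons = {}
    for m1, m2 in (("GMSI", "SIB"), ("GMSI", "AUM_A"), ("AUM_F", "AUM_A"), ("DIN", "SIB")):
        try:
            comparisons[f"{m1}-vs-{m2}"] = bootstrap_corr_diff(
                wide,
                (f"{m1}_inperson", f"{m1}_web"),
                (f"{m2}_inperson", f"{m2}_web"),
                B=analysis.bootstrap_B, rng=rng, alpha=analysis.alpha,
            )
        except (ValidationError, InsufficientDataError) as exc:
            log.warning("bootstrap comparison %s vs %s skipped: %s", m1, m2, exc)

    def steiger_block(covariate: str) -> dict:
        out = {}
        for m in MEASURES:
            sub = wide[[covariate, f"{m}_inperson", f"{m}_web"]].dropna()
            if len(sub) < 5:
                continue
            r_jk = np.corrcoef(sub[covariate], sub[f"{m}_inperson"])[0, 1]
            r_jh = np.corrcoef(sub[covariate], sub[f"{m}_web"])[0, 1]
            r_kh = np.corrcoef(sub[f"{m}_inperson"], sub[f"{m}_web"])[0, 1]
            out[m] = steiger_dependent_corr(r_jk, r_jh, r_kh, len(sub))
        return out

    steiger_age = steiger_block("age") if "age" in wide.columns else {}
    steiger_pta = steiger_block("pta_hf") if "pta_hf" in wide.columns else {}

    # participation tests: proportion above 70 and moderate-vs-severe split,
    # in-person group vs web group
    chi = {}
    inperson_mask = wide["GMSI_inperson"].notna()
    web_mask = wide["GMSI_web"].notna()
    if "age" in wide.columns:
        older = wide["age"] > 70
        table = [
            [int((inperson_mask & ~older).sum()), int((inperson_mask & older).sum())],
            [int((web_mask & ~older).sum()), int((web_mask & older).sum())],
        ]
        try:
            chi["age_gt70_by_group"] = chi_square_2x2(table)
        except ValidationError:
            pass
    if "hearing_category" in measures.columns:
        cat = measures.groupby("participant_id")["hearing_category"].first()
        merged = wide.set_index("participant_id").join(cat)
        counts = {}
        for group, mask in (
            ("inperson", merged["GMSI_inperson"].notna()),
            ("web", merged["GMSI_web"].notna()),
        ):
            counts[group] = [
                int(((merged["hearing_category"] == "moderate") & mask).sum()),
                int(((merged["hearing_category"] == "severe") & mask).sum()),
            ]
        try:
            chi["moderate_vs_severe_by_group"] = chi_square_2x2(
                [counts["inperson"], counts["web"]]
            )
        except ValidationError:
            pass

    associations = []
    for name, (mx, my) in (("SIB~AUM_A", ("SIB", "AUM_A")), ("GMSI~AUM_F", ("GMSI", "AUM_F"))):
        for setting in ("inperson", "web"):
            sub = measures.loc[measures["setting"] == setting, [mx, my] + (
                ["age"] if "age" in measures.columns else []
            )].dropna(subset=[mx, my])
            if len(sub) < 5:
                continue
            pr = pearson_with_ci(sub[mx], sub[my], alpha=analysis.alpha)
            partial = None
            if "age" in sub.columns:
                complete = sub.dropna()
                if len(complete) >= 5:
                    partial = partial_corr(complete[mx], complete[my], complete["age"])
            associations.append(
                AssociationRow(name=name, setting=setting, pearson=pr, partial_age=partial)
            )

    return ReliabilityReport(
        reliability=reliability,
        bootstrap_comparisons=comparisons,
        steiger_vs_age=steiger_age,
        steiger_vs_pta=steiger_pta,
        chi_square=chi,
        associations=associations,
    )


def render_report(report: ReliabilityReport) -> str:
    """Human-readable report; the first block mirrors the published table layout."""
    lines = []
    lines.append("Test-retest reliability (paired participants)")
    lines.append(f"{'measure':8s} {'in-person mean (SD)':>22s} {'web mean (SD)':>20s} {'r':>6s} {'ICC':>6s} {'n':>4s}")
    for rel in report.reliability:
        lines.append(
            f"{rel.measure:8s} {rel.mean_inperson:12.2f} ({rel.sd_inperson:5.2f}) "
            f"{rel.mean_web:11.2f} ({rel.sd_web:5.2f}) {rel.pearson.r:6.2f} "
            f"{rel.icc.icc:6.2f} {rel.n:4d}"
        )
    lines.append("")
    lines.append("Bootstrap differences between retest correlations (95% CI)")
    for name, b in report.bootstrap_comparisons.items():
        flag = "*" if b.significant else " "
        lines.append(
            f"  {name:16s} mean diff {b.mean_diff:+.2f} "
            f"[{b.ci_low:+.2f}, {b.ci_high:+.2f}]{flag} (B={b.B}, n={b.n})"
        )
    for label, block in (("age", report.steiger_vs_age), ("PTA", report.steiger_vs_pta)):
        if not block:
            continue
        lines.append("")
        lines.append(f"Steiger tests: correlation with {label}, in-person vs web")
        for m, s in block.items():
            lines.append(
                f"  {m:8s} t({s.df}) = {s.statistic:+.3f}, p = {s.p_value:.3f} "
                f"(r_in={s.r_jk:+.2f}, r_web={s.r_jh:+.2f})"
            )
    if report.chi_square:
        lines.append("")
        lines.append("Chi-square participation tests")
        for name, c in report.chi_square.items():
            lines.append(f"  {name:28s} chi2({c.df}) = {c.statistic:.2f}, p = {c.p_value:.3f}")
    if report.associations:
        lines.append("")
        lines.append("Cross-measure associations")
        for a in report.associations:
            extra = ""
            if a.partial_age is not None:
                extra = f"; age-controlled r = {a.partial_age.r:+.2f}"
            lines.append(
                f"  {a.name:12s} [{a.setting:8s}] r = {a.pearson.r:+.2f} "
                f"[{a.pearson.ci_low:+.2f}, {a.pearson.ci_high:+.2f}], "
                f"p = {a.pearson.p_value:.4f}, n = {a.pearson.n}{extra}"
            )
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig, outdir=None, collect_trials: bool = True) -> ReliabilityReport:
    """Simulate one study and analyze it; optionally write all artifacts.

    Writes ``cohort.csv``, ``measures.csv``, ``trials.csv``, ``results.csv``
    and ``report.txt`` to ``outdir`` when given.  Deterministic for a fixed
    config and seed.
    """
    log.info("simulating study (seed=%d)", config.seed)
    cohort_df, measures_df, trials_df = simulate_measures(config, collect_trials=collect_trials)
    log.info(
        "cohort n=%d, sessions=%d", len(cohort_df), len(measures_df)
    )
    rng = task_rng(config.seed, 0, "session", setting="inperson", task="param")
    report = analyze_measures(measures_df, config.analysis, rng=rng)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        cohort_df.to_csv(out / "cohort.csv", index=False)
        measures_df.to_csv(out / "measures.csv", index=False)
        if trials_df is not None:
            trials_df.to_csv(out / "trials.csv", index=False)
        report.to_frame().to_csv(out / "results.csv", index=False)
        (out / "report.txt").write_text(render_report(report))
        log.info("artifacts written to %s", out)
    return report


def replicate_summary(config: RunConfig, replicates: int | None = None) -> pd.DataFrame:
    """Monte-Carlo summary over replicate studies.

    Re-simulates the study ``replicates`` times with derived seeds and returns
    one row per replicate with the retest correlation of each measure plus the
    paired-sample size; a trailing ``mean`` row averages the correlations.
    """
    replicates = replicates or config.replicates
    rows = []
    for rep in range(replicates):
        _, measures_df, _ = simulate_measures(config, seed=config.seed + rep)
        measures_df = preprocess(
            measures_df, log_columns=list(PRECISION_MEASURES), z_columns=[]
        )
        wide = _wide_measures(measures_df)
        row = {"replicate": rep}
        for m in MEASURES:
            pairs = wide[[f"{m}_inperson", f"{m}_web"]].dropna()
            row[f"r_{m}"] = float(np.corrcoef(pairs.iloc[:, 0], pairs.iloc[:, 1])[0, 1])
            row["n_pairs"] = len(pairs)
        rows.append(row)
    df = pd.DataFrame(rows)
    mean_row = {"replicate": "mean"}
    for m in MEASURES:
        mean_row[f"r_{m}"] = float(df[f"r_{m}"].mean())
    mean_row["n_pairs"] = float(df["n_pairs"].mean())
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
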