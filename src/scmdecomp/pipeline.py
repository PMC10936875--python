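"""Orchestration: configuration, staged execution, and report bundles.

A run executes  collapse -> pool restriction -> joint weight fit ->
jackknife inference -> subgroup decomposition -> robustness battery  and
writes a reproducible bundle (fit JSON, gap-series CSVs, decomposition
CSV, robustness JSON, run log).  Identical config + seed produce
byte-identical JSON/CSV outputs; timestamps are confined to the log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .decomposition import decompose_fit, subgroup_panel_from_students
from .errors import ConfigError, MissingDataError, ScmDecompError
from .inference import jackknife_se, twfe_att_se, twfe_equality_test
from .panel import collapse_to_panel, ses_index
from .pool import PRESETS, PoolRule, restrict_pool
from .scm import fit_scm
from .simulate import SyntheticConfig, generate_panel, generate_students

log = logging.getLogger("scmdecomp")

@dataclass
class PipelineConfig:
    """Declarative description of one analysis run."""

    outdir: str = "results"
    seed: int = 0
    treatment_year: int = 2015
    treated_id: str | None = None
    panel_csv: str | None = None
    students_csv: str | None = None
    covariates_csv: str | None = None
    simulate: SyntheticConfig | None = None
    pool_preset: str = "U90"
    custom_rule: PoolRule | None = None
    outcomes: tuple | None = None  # outcome subset used for the weight fit
    assignment: str = "contemporaneous"
    base_year: int = 2014
    subgroup_variables: tuple = ("gender", "grade_band", "ses", "mobility", "service_line")
    log_level: str = "INFO"

    def __post_init__(self):
        if self.pool_preset not in set(PRESETS) | {"custom"}:
            raise ConfigError(f"unknown pool preset {self.pool_preset!r}")
        if self.pool_preset == "custom" and self.custom_rule is None:
            raise ConfigError("custom pool preset requires custom_rule")
        for path in (self.panel_csv, self.students_csv, self.covariates_csv):
            if path is not None and not Path(path).exists():
                raise ConfigError(f"input path does not exist: {path}")
        if self.panel_csv is None and self.students_csv is None and self.simulate is None:
            self.simulate = SyntheticConfig()

    @property
    def pool_rule(self) -> PoolRule:
        return self.custom_rule if self.pool_preset == "custom" else PRESETS[self.pool_preset]

    def to_jsonable(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): convert(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [convert(v) for v in obj]
            return obj

        return convert(self)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (where output lands and how
        chattily we log are excluded, so relocated re-runs hash alike)."""
        payload = self.to_jsonable()
        payload.pop("outdir", None)
        payload.pop("log_level", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        if isinstance(sim, dict):
            raw["simulate"] = SyntheticConfig(**sim)
        rule = raw.pop("custom_rule", None)
        if isinstance(rule, dict):
            raw["custom_rule"] = PoolRule(**rule)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def _load_inputs(config: PipelineConfig, outdir: Path) -> dict:
    """Load or simulate the panel, student records, and covariate table."""
    data: dict = {"records": None, "covariates": None, "truth": None}
    if config.simulate is not None and config.panel_csv is None and config.students_csv is None:
        sim = config.simulate
        log.info("simulating panel and students (seed=%d)", config.seed)
        panel, covariates, truth = generate_panel(sim, config.seed)
        records, _ = generate_students(sim, config.seed)
        data.update(
            panel=panel,
            records=records,
            covariates=covariates,
            truth=truth,
            treated_id=sim.treated_id,
        )
        panel.to_csv(outdir / "panel.csv", index=False)
        records.to_csv(outdir / "students.csv", index=False)
        covariates.to_csv(outdir / "covariates.csv", index=False)
        truth_dict = {
            "att": truth.att,
            "subgroup_att": truth.subgroup_att,
            "hull_weights": truth.hull_weights,
        }
        (outdir / "truth.json").write_text(json.dumps(truth_dict, sort_keys=True, indent=1))
        return data

    if config.treated_id is None:
        raise ConfigError("treated_id is required when reading data from files")
    data["treated_id"] = config.treated_id
    if config.students_csv is not None:
        records = pd.read_csv(config.students_csv, float_precision="round_trip")
        data["records"] = records
        data["panel"] = collapse_to_panel(
            records, config.treatment_year, config.assignment, config.base_year
        )
    else:
        data["panel"] = pd.read_csv(config.panel_csv, float_precision="round_trip")
    if config.covariates_csv is not None:
        data["covariates"] = pd.read_csv(config.covariates_csv, float_precision="round_trip")
    return data


def _select_pool(config: PipelineConfig, data: dict, rule: PoolRule | None = None) -> list:
    rule = rule or config.pool_rule
    panel_units = set(data["panel"]["unit"].unique()) - {data["treated_id"]}
    if data["covariates"] is None:
        log.info("no covariate table; donor pool = all %d panel controls", len(panel_units))
        return sorted(panel_units, key=str)
    result = restrict_pool(data["covariates"], rule, data["treated_id"])
    pool = [u for u in result.controls if u in panel_units]
    log.info(
        "pool rule %s/%s: %d districts (cutoffs %s)",
        rule.combinator,
        rule.percentile,
        len(pool),
        {k: round(v, 4) for k, v in result.cutoffs.items()},
    )
    if not pool:
        raise MissingDataError("restricted pool shares no districts with the panel")
    return pool


def _fit_stage(config: PipelineConfig, data: dict, panel=None, outcomes=None):
    panel = data["panel"] if panel is None else panel
    pool = data["pool"]
    fit = fit_scm(
        panel,
        data["treated_id"],
        pool,
        outcome_subset=outcomes if outcomes is not None else config.outcomes,
        treatment_year=config.treatment_year,
    )
    inference = jackknife_se(
        panel,
        data["treated_id"],
        pool,
        outcome_subset=outcomes if outcomes is not None else config.outcomes,
        treatment_year=config.treatment_year,
        full_fit=fit,
    )
    return fit, inference


def _decomposition_stage(config: PipelineConfig, data: dict, fit) -> pd.DataFrame:
    records = data["records"]
    treated = data["treated_id"]
    panel = data["panel"]
    ses_labels = None
    if "ses" in config.subgroup_variables:
        flint = records[records["district_of_residence"] == treated]
        ses_labels = ses_index(flint).labels
    rows = []
    for outcome in fit.outcomes:
        control_values = panel[
            (panel["outcome"] == outcome) & (panel["unit"] != treated)
        ][["unit", "year", "value"]]
        for variable in config.subgroup_variables:
            try:
                sp = subgroup_panel_from_students(
                    records,
                    variable,
                    outcome,
                    treated,
                    config.treatment_year,
                    ses_labels=ses_labels,
                )
                dec = decompose_fit(fit, sp)
                test = twfe_equality_test(
                    control_values,
                    fit.weights,
                    pd.DataFrame({"s0": sp.means[0], "s1": sp.means[1]}),
                    config.treatment_year,
                )
                dec.equality_p = test.pvalue
                _, dec.se_s0 = twfe_att_se(
                    control_values, fit.weights, sp.means[0], config.treatment_year
                )
                _, dec.se_s1 = twfe_att_se(
                    control_values, fit.weights, sp.means[1], config.treatment_year
                )
            except ScmDecompError as exc:
                log.warning("decomposition %s/%s skipped: %s", variable, outcome, exc)
                continue
            rows.extend(dec.to_rows())
    return pd.DataFrame(rows)


def run_robustness(config: PipelineConfig, data: dict) -> dict:
    """The robustness battery: invariant assignment, alternative pools,
    and single-/double-outcome weight fits, each reported like the original."""
    out = {}
    fitted_outcomes = None

    def summarize(fit, inference):
        return {
            "att": {k: float(v) for k, v in fit.att.items()},
            "se": {k: float(v) for k, v in inference.se.items()},
            "pre_rmse": {k: float(v) for k, v in fit.pre_rmse.items()},
            "weights": fit.weights.as_dict(),
        }

    fit, inference = _fit_stage(config, data)
    out["original"] = summarize(fit, inference)
    fitted_outcomes = list(fit.outcomes)

    if data.get("records") is not None:
        inv_panel = collapse_to_panel(
            data["records"], config.treatment_year, "invariant", config.base_year
        )
        inv_data = dict(data, panel=inv_panel)
        inv_data["pool"] = [u for u in data["pool"] if u in set(inv_panel["unit"])]
        fit_i, inf_i = _fit_stage(config, inv_data, panel=inv_panel)
        out["invariant"] = summarize(fit_i, inf_i)

    if data.get("covariates") is not None:
        for preset in ("I75", "U95"):
            alt = dict(data)
            try:
                alt["pool"] = _select_pool(config, data, rule=PRESETS[preset])
                fit_a, inf_a = _fit_stage(config, alt)
            except ScmDecompError as exc:
                log.warning("robustness pool %s skipped: %s", preset, exc)
                continue
            out[preset] = summarize(fit_a, inf_a)

    for outcome in fitted_outcomes:
        fit_s, inf_s = _fit_stage(config, data, outcomes=[outcome])
        out[f"single_{outcome}"] = summarize(fit_s, inf_s)
    pairs = [
        ("double_achievement", [o for o in ("math", "reading") if o in fitted_outcomes]),
        (
            "double_status",
            [o for o in ("special_needs", "attendance") if o in fitted_outcomes],
        ),
    ]
    for name, subset in pairs:
        if len(subset) == 2:
            fit_d, inf_d = _fit_stage(config, data, outcomes=subset)
            out[name] = summarize(fit_d, inf_d)
    return out


# ---------------------------------------------------------------------------
# Entry point
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, robustness: bool = True) -> dict:
    """Execute every stage and write the report bundle; returns file paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level)
    bundle = {"outdir": str(outdir)}
    try:
        log.info("config hash %s seed %d", config.config_hash(), config.seed)
        stage = "load"
        data = _load_inputs(config, outdir)
        stage = "pool"
        data["pool"] = _select_pool(config, data)
        stage = "fit"
        fit, inference = _fit_stage(config, data)
        report = fit.to_dict()
        report["inference"] = inference.to_dict()
        report["pool"] = [str(u) for u in data["pool"]]
        report["config_hash"] = config.config_hash()
        report["seed"] = config.seed
        (outdir / "fit.json").write_text(json.dumps(report, sort_keys=True, indent=1))
        bundle["fit"] = str(outdir / "fit.json")
        for outcome, gaps in fit.gaps.items():
            path = outdir / f"gaps_{outcome}.csv"
            gaps.rename_axis("year").reset_index().to_csv(path, index=False)
            bundle[f"gaps_{outcome}"] = str(path)
        if data.get("records") is not None:
            stage = "decomposition"
            table = _decomposition_stage(config, data, fit)
            table.to_csv(outdir / "decomposition.csv", index=False)
            bundle["decomposition"] = str(outdir / "decomposition.csv")
        if robustness:
            stage = "robustness"
            rb = run_robustness(config, data)
            (outdir / "robustness.json").write_text(json.dumps(rb, sort_keys=True, indent=1))
            bundle["robustness"] = str(outdir / "robustness.json")
        log.info("pipeline complete: %s", sorted(bundle))
        return bundle
    except ScmDecompError as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise ScmDecompError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
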