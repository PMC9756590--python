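"""End-to-end pipeline: simulate -> elicit -> fit all three stages -> report.

Also provides the sample-flow (recruitment funnel) arithmetic: view rate,
participation rate, refusal rate among otherwise-eligible screeners, and
completion rate, each rounded half-up to one decimal as percentages.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__, cohort as cohort_mod, initial_decision, latent_class, membership as membership_mod
from .cohort import SyntheticCohort, dummy_matrix
from .initial_decision import ModelError

STAGES = ("cohort", "initial", "lcl", "membership")


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (so 86.85 -> 86.9, not banker's 86.8)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: float, denominator: float, decimals: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up; NaN when undefined."""
    if denominator == 0:
        return float("nan")
    return round_half_up(100.0 * numerator / denominator, decimals)


def summarize_flow(
    invited: int,
    viewed: int,
    consented: int,
    completed: int,
    otherwise_eligible: int | None = None,
    refusers: int | None = None,
) -> pd.DataFrame:
    """Recruitment funnel rate table.

    Completion rate = completed / consented; refusal ('definitely not')
    rate = refusers / otherwise eligible; view rate = viewed / invited;
    participation rate = consented / invited.  Counts must be non-negative
    and non-increasing down the funnel.  Undefined rates (zero denominator)
    are flagged.
    """
    counts = [invited, viewed, consented, completed]
    if any(c < 0 for c in counts):
        raise ValueError("funnel counts must be non-negative")
    if not invited >= viewed >= consented >= completed:
        raise ValueError("funnel counts must be non-increasing: "
                         f"{invited} >= {viewed} >= {consented} >= {completed}")
    rows = [
        ("view_rate", viewed, invited),
        ("participation_rate", consented, invited),
        ("completion_rate", completed, consented),
    ]
    if otherwise_eligible is not None and refusers is not None:
        if refusers > otherwise_eligible:
            raise ValueError("refusers cannot exceed otherwise-eligible count")
        rows.append(("definitely_not_rate", refusers, otherwise_eligible))
    table = pd.DataFrame(rows, columns=["rate", "numerator", "denominator"])
    table["pct"] = [
        percentage(num, den) for num, den in zip(table.numerator, table.denominator)
    ]
    table["undefined"] = table["pct"].isna()
    return table


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    n: int = cohort_mod.DEFAULT_N
    quotas: Mapping[str, int] | None = None
    truth: str | Mapping | None = None
    schema: str | Mapping | None = None
    stages: Sequence[str] = STAGES
    outdir: str | Path = "pipeline_out"
    class_range: Sequence[int] = (2, 3, 4, 5)
    n_starts: int = 20
    folds: int = 10

    def __post_init__(self) -> None:
        stages = tuple(self.stages)
        if stages != STAGES[: len(stages)]:
            raise PipelineError(
                f"stages {stages} must be a prefix of {STAGES}"
            )
        self.stages = stages

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        raw.update(overrides)
        return cls(**raw)

    def hash(self) -> str:
        # outdir is storage, not part of the scientific configuration
        payload = {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in self.__dict__.items()
            if k != "outdir"
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunReport:
    """Summaries of every executed stage, plus provenance metadata."""

    config: PipelineConfig
    version: str = __version__
    stage_summaries: dict = field(default_factory=dict)
    file_hashes: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, pd.DataFrame):
                return o.to_dict(orient="records")
            if isinstance(o, Path):
                return str(o)
            return str(o)

        return json.dumps(
            {
                "version": self.version,
                "config": self.config.__dict__,
                "config_hash": self.config.hash(),
                "stage_summaries": self.stage_summaries,
                "file_hashes": self.file_hashes,
                "timings_s": self.timings,
            },
            indent=1,
            default=default,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_table(
    df: pd.DataFrame, path: Path, config: PipelineConfig, report: RunReport
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# seed={config.seed} config_hash={config.hash()}\n")
        df.to_csv(fh, index=False)
    report.file_hashes[path.name] = _sha256(path)


def run(config: PipelineConfig) -> RunReport:
    """Execute the configured pipeline stages in dependency order.

    Stages: cohort (simulate covariates + adaptive elicitation + decisions),
    initial (three logistic variants), lcl (class-count selection and odds
    ratios), membership (beta regression of class-2 posteriors).  Outputs
    are CSV/JSON files under ``config.outdir``, each carrying the seed and
    config hash in a metadata header.  Identical (config, seed) pairs are
    bit-reproducible.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config)
    ss = np.random.SeedSequence(config.seed)
    sub = {name: s for name, s in zip(STAGES, ss.spawn(len(STAGES)))}

    syn: SyntheticCohort | None = None
    lcl_fit = None
    lcl_data = None
    current = "cohort"
    try:
        for current in config.stages:
            t0 = time.perf_counter()
            if current == "cohort":
                syn = cohort_mod.generate_cohort(
                    {
                        "n": config.n,
                        "quotas": config.quotas,
                        "truth": config.truth,
                        "schema": config.schema,
                    },
                    seed=int(sub["cohort"].generate_state(1)[0] % 2**31),
                )
                paths = syn.to_csv(
                    outdir, f"seed={config.seed} config_hash={config.hash()}"
                )
                for p in paths.values():
                    report.file_hashes[p.name] = _sha256(p)
                acc = syn.responses.query("task_index == 0")["decision"].mean()
                report.stage_summaries["cohort"] = {
                    "n_respondents": int(config.n),
                    "initial_acceptance_pct": round(100 * float(acc), 2),
                    "class_counts": {
                        int(k): int(v)
                        for k, v in zip(*np.unique(syn.class_labels, return_counts=True))
                    },
                }
            elif current == "initial":
                decisions = (
                    syn.responses.query("task_index == 0")
                    .sort_values("respondent_id")["decision"]
                    .to_numpy()
                )
                fits, table = initial_decision.compare_variants(
                    syn.covariates,
                    decisions,
                    folds=config.folds,
                    rng=int(sub["initial"].generate_state(1)[0] % 2**31),
                )
                _write_table(table, outdir / "initial_model_comparison.csv", config, report)
                for name, fit in fits.items():
                    _write_table(
                        fit.table().rename_axis("dummy").reset_index(),
                        outdir / f"initial_{name}.csv",
                        config,
                        report,
                    )
                report.stage_summaries["initial"] = table
            elif current == "lcl":
                lcl_data = latent_class.build_lcl_data(syn.responses)
                lcl_fit, comparison = latent_class.select_n_classes(
                    lcl_data,
                    candidate_range=config.class_range,
                    n_starts=config.n_starts,
                    rng=int(sub["lcl"].generate_state(1)[0] % 2**31),
                )
                or_table = latent_class.odds_ratios(lcl_fit)
                W = lcl_fit.posterior
                posterior_df = pd.DataFrame(
                    W, columns=[f"class_{c + 1}" for c in range(W.shape[1])]
                )
                posterior_df.insert(0, "respondent_id", lcl_data.respondent_ids)
                summary = latent_class.switch_summary(lcl_data, W)
                _write_table(comparison, outdir / "lcl_model_comparison.csv", config, report)
                _write_table(or_table, outdir / "lcl_or_table.csv", config, report)
                _write_table(posterior_df, outdir / "lcl_posterior.csv", config, report)
                report.stage_summaries["lcl"] = {
                    "selected_classes": lcl_fit.n_classes,
                    "class_shares": lcl_fit.class_shares,
                    "bic": lcl_fit.bic,
                    "pct_tasks_switched": summary.pct_tasks_switched,
                    "pct_never_switched": summary.pct_never_switched,
                    "pct_always_switched": summary.pct_always_switched,
                    "per_class_switch_rates": summary.per_class_switch_rates,
                }
            elif current == "membership":
                if lcl_fit.n_classes < 2:
                    raise ModelError("membership stage needs >= 2 classes")
                # outcome: posterior probability of the largest-share class
                y = lcl_fit.posterior[:, -1]
                y = membership_mod.squeeze_to_open_interval(y)
                Z = dummy_matrix(syn.covariates)
                beta_fit = membership_mod.fit_beta_regression(y, Z)
                _write_table(
                    membership_mod.membership_table(beta_fit)
                    .rename_axis("dummy")
                    .reset_index(),
                    outdir / "membership_table.csv",
                    config,
                    report,
                )
                report.stage_summaries["membership"] = {
                    "precision_phi": beta_fit.precision,
                    "log_likelihood": beta_fit.log_likelihood,
                    "n_significant_p05": int((beta_fit.p_values < 0.05).sum()),
                }
            report.timings[current] = round(time.perf_counter() - t0, 3)
    except Exception as exc:
        (outdir / f"{current}.failed").write_text(
            f"stage {current} failed: {exc}\n", encoding="utf-8"
        )
        raise PipelineError(f"stage {current!r} failed: {exc}") from exc

    (outdir / "report.json").write_text(report.to_json(), encoding="utf-8")
    return report
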