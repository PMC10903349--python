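"""End-to-end analysis orchestration.

``run_full_analysis`` chains the pipeline -- event ingestion, encounter
histories, POPAN model set with c-hat-adjusted QAICc ranking and
averaging, dispersal statistics and kernels, behaviour and wing-condition
tests -- and writes every table as CSV/JSON plus a run manifest recording
inputs, decisions (c-hat used, interval chosen, dedup mode) and hashes, so
a bundle is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behaviour as bh
from . import dispersal as dsp
from .events import build_encounter_histories, read_events, recapture_summary, write_inp
from .popan import PopanEstimator, estimate_chat, model_average_abundance, model_table

__all__ = ["AnalysisConfig", "run_full_analysis"]

DEFAULT_MODEL_SET = (
    "Phi(.) p(.) pent(T^2) N(g)",
    "Phi(.) p(g) pent(T^2) N(g)",
    "Phi(.) p(g) pent(g*T^2) N(g)",
    "Phi(g+T) p(g) pent(g*T^2) N(g)",
)


@dataclass
class AnalysisConfig:
    """Declarative configuration of one full pipeline run."""

    events_path: str
    out_dir: str
    generation: int | None = None
    mask_occasions: list[str] = field(default_factory=list)  # ISO dates
    model_set: tuple[str, ...] = DEFAULT_MODEL_SET
    chat_policy: str = "none"  # none | manual | bootstrap | deviance_df
    chat_value: float = 1.0  # used when chat_policy == "manual"
    chat_bootstrap_B: int = 100
    clamp_chat: bool = False
    average_best: int | None = 4
    kernel_widths: tuple[float, ...] = (20.0, 30.0, 50.0)
    distance_statistic: str = "displacement_m"  # or max_displacement_m
    behaviour_categories: tuple[str, ...] | None = None
    schema: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run the whole pipeline; returns the manifest dict.

    Report files written to ``config.out_dir``: recapture summary, model
    comparison table, daily abundance (model-averaged when configured),
    displacement summary, R^2 grid, extrapolation table, statistical test
    summaries and the run manifest. Any stage failure removes partial
    outputs and re-raises with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "inputs": {"events": {"path": str(config.events_path),
                              "sha256": _sha(Path(config.events_path))}},
        "started": dt.datetime.now().isoformat(timespec="seconds"),
        "stages": {},
        "decisions": {},
    }
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        p = out / name
        df.to_csv(p, index=False)
        written.append(p)

    stage = "read_events"
    try:
        events = read_events(config.events_path, schema=config.schema or None)
        mask = [dt.date.fromisoformat(d) for d in config.mask_occasions]
        stage = "encounter_histories"
        hist = build_encounter_histories(events, generation=config.generation,
                                         mask_occasions=mask)
        emit("recapture_summary.csv", recapture_summary(hist))
        write_inp(hist, out / "histories.inp")
        written.append(out / "histories.inp")
        manifest["stages"]["histories"] = {
            "n_individuals": hist.n_individuals,
            "n_occasions": hist.n_occasions,
            "n_dropped_masked": hist.n_dropped,
        }

        stage = "popan"
        rng = np.random.default_rng(config.seed)
        fits = []
        for i, label in enumerate(config.model_set):
            fits.append(
                PopanEstimator(formula=label, clamp_chat=config.clamp_chat,
                               random_state=int(rng.integers(2**31 - 1))).fit(hist)
            )
        general = max(fits, key=lambda f: f.n_params_)
        if config.chat_policy == "none":
            chat = 1.0
        elif config.chat_policy == "manual":
            chat = estimate_chat(general, method="manual", manual=config.chat_value)
        else:
            chat = estimate_chat(general, hist, method=config.chat_policy,
                                 B=config.chat_bootstrap_B,
                                 seed=int(rng.integers(2**31 - 1)))
        if config.clamp_chat and chat < 1.0:
            chat = 1.0
        manifest["decisions"]["chat"] = {"policy": config.chat_policy, "value": chat}
        tab = model_table(fits, chat=chat)
        emit("model_table.csv", tab.drop(columns="_fit"))
        if config.average_best and len(fits) > 1:
            avg = model_average_abundance(fits, subset=min(config.average_best, len(fits)),
                                          chat=chat)
            daily = avg["daily"]
            manifest["stages"]["popan"] = {
                "averaged_models": avg["models"],
                "weights": avg["weights"].tolist(),
                "nhat": dict(zip(avg["groups"], np.round(avg["nhat"], 2))),
                "nhat_se": dict(zip(avg["groups"], np.round(avg["nhat_se"], 2))),
            }
        else:
            bestfit = tab["_fit"].iloc[0]
            daily = bestfit.derived_abundance()
            manifest["stages"]["popan"] = {
                "best_model": bestfit.spec_.label(),
                "nhat": dict(zip(bestfit.group_names_, np.round(bestfit.nhat_, 2))),
                "nhat_se": dict(zip(bestfit.group_names_, np.round(bestfit.nhat_se_, 2))),
            }
        emit("daily_abundance.csv", daily)
        best_params = {
            f.spec_.label(): {"beta": f.beta_.tolist(), "loglik": f.loglik_,
                              "converged": f.converged_}
            for f in fits
        }
        (out / "popan_fits.json").write_text(json.dumps(best_params, indent=1))
        written.append(out / "popan_fits.json")
        best_daily = tab["_fit"].iloc[0].derived_abundance(require_convergence=False)
        mdf = best_daily[best_daily.group == "male"]
        fdf = best_daily[best_daily.group == "female"]
        if len(mdf) and len(fdf):
            try:
                manifest["stages"]["protandry_offset_days"] = bh.protandry_index(mdf, fdf)
            except ValueError:
                manifest["stages"]["protandry_offset_days"] = None

        stage = "dispersal"
        rec = dsp.displacement_table(events, generation=config.generation)
        emit("displacement_summary.csv", dsp.displacement_summary(rec))
        sel = dsp.select_best_fit(rec, config.kernel_widths,
                                  statistic=config.distance_statistic)
        emit("r2_grid.csv", sel["grid"])
        manifest["decisions"]["kernel"] = {
            kind: {"interval_width": f.interval_width_, "r2": f.r2_}
            for kind, f in sel["best"].items()
        } | {"notes": sel["notes"], "statistic": config.distance_statistic}
        extra = pd.concat(
            [dsp.extrapolate_proportion(f) for f in sel["best"].values()],
            ignore_index=True,
        )
        emit("extrapolation.csv", extra)

        stage = "behaviour"
        tests = []
        tabb = bh.first_record_table(events, "sex", "behaviour", dedup=True,
                                     categories=config.behaviour_categories)
        manifest["decisions"]["behaviour_dedup"] = True
        res = bh.chi_squared_homogeneity(tabb)
        tests.append({"test": "behaviour_by_sex_chi2", **res})
        tabb.to_csv(out / "behaviour_table.csv")
        written.append(out / "behaviour_table.csv")
        wing_series = {}
        for sex in ("male", "female"):
            try:
                s = bh.daily_wing_means(events, sex)
            except ValueError:
                continue
            wing_series[sex] = s
            emit(f"wing_series_{sex}.csv", s)
            try:
                reg = bh.wing_decay_regression(s)
                tests.append({"test": f"wing_decay_{sex}", **reg})
            except ValueError:
                pass
        if len(wing_series) == 2:
            try:
                sd = bh.slope_difference_test(wing_series["male"], wing_series["female"])
                tests.append({"test": "wing_slope_sex_interaction", **sd})
            except ValueError:
                pass
        d_m = rec[rec.sex == "male"]["displacement_m"]
        d_f = rec[rec.sex == "female"]["displacement_m"]
        if len(d_m) and len(d_f):
            mw = bh.mann_whitney_u(d_m, d_f)
            tests.append({"test": "displacement_sex_mannwhitney", **mw})
        for sex, sub in rec.groupby("sex"):
            try:
                dtr = dsp.distance_time_regression(sub)
                tests.append({"test": f"distance_vs_days_{sex}", **dtr})
            except ValueError:
                pass
        emit("test_summaries.csv", pd.DataFrame(tests))
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest["outputs"] = {p.name: _sha(p) for p in sorted(written)}
    manifest["finished"] = dt.datetime.now().isoformat(timespec="seconds")
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
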