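"""Full-analysis orchestration: all traits x five grouping hypotheses.

For each trait the pipeline fits the five genetic hypotheses with the
configured covariance structure, warm-starting finer groupings from the
best coarser solution so that the maximized likelihoods respect the
nesting order (a finer partition can never fit worse than a coarsening it
refines).  Results are collected into an :class:`AnalysisReport` holding
per-trait selection tables, best-model estimates with confidence
intervals, derived allocation statistics and run metadata, and can be
rendered as delimited text, structured JSON or a human-readable summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import params as libparams
from .data import Dataset
from .fitting import CovarianceSpec, FitControl, FitResult, ModelSpec, \
    fit_gnls
from .grouping import GroupingScheme, all_schemes, is_coarsening
from .selection import compare_fits
from .traits import allocation_per_gram, remobilization_efficiency

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "fit_schemes",
    "run_full_analysis",
    "render_report",
    "report_from_json",
]

logger = logging.getLogger(__name__)

# fitting order: every scheme is warm-started from the best coarsening
# already fitted (UNI coarsens everything; GEN4 refines everything)
_FIT_ORDER = ("UNI", "MAPHE", "MAHY", "GEN3", "GEN4")


@dataclass
class AnalysisConfig:
    """Trait-to-family mapping, covariance choices and fit control."""

    trait_family: Mapping[str, str] = field(
        default_factory=lambda: dict(libparams.TRAIT_FAMILY))
    destructive_traits: frozenset = libparams.DESTRUCTIVE_TRAITS
    seed_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(libparams.SEED_WEIGHT_BY_CLASS))
    control: FitControl = field(default_factory=FitControl)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "trait_family" in raw:
            kwargs["trait_family"] = dict(raw["trait_family"])
        if "destructive_traits" in raw:
            kwargs["destructive_traits"] = frozenset(
                raw["destructive_traits"])
        if "seed_weights" in raw:
            kwargs["seed_weights"] = dict(raw["seed_weights"])
        if "control" in raw:
            kwargs["control"] = FitControl(**raw["control"])
        return cls(**kwargs)

    def covariance_for(self, trait: str, family: str) -> CovarianceSpec:
        if trait in self.destructive_traits:
            variance = "per_stratum" if family == "decay" else "exponential"
            return CovarianceSpec(correlation="independent",
                                  variance=variance)
        return CovarianceSpec(correlation="ar1", variance="exponential")


@dataclass
class AnalysisReport:
    """Everything the analysis computed, reproducible from config + data."""

    selection: dict            # trait -> selection DataFrame
    estimates: dict            # trait -> best-model estimates DataFrame
    best_scheme: dict          # trait -> scheme name
    allocation: pd.DataFrame   # derived per-gram / efficiency statistics
    metadata: dict

    def to_json(self) -> str:
        def frame(df):
            d = df.to_dict(orient="split")
            d.pop("index", None)
            return d

        payload = {
            "selection": {t: frame(df)
                          for t, df in self.selection.items()},
            "estimates": {t: frame(df)
                          for t, df in self.estimates.items()},
            "best_scheme": self.best_scheme,
            "allocation": frame(self.allocation),
            "metadata": self.metadata,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def report_from_json(text: str) -> AnalysisReport:
    raw = json.loads(text)

    def frame(d):
        return pd.DataFrame(d["data"], columns=d["columns"])

    return AnalysisReport(
        selection={t: frame(d) for t, d in raw["selection"].items()},
        estimates={t: frame(d) for t, d in raw["estimates"].items()},
        best_scheme=dict(raw["best_scheme"]),
        allocation=frame(raw["allocation"]),
        metadata=dict(raw["metadata"]),
    )


def _expand_start(coarse: GroupingScheme, estimates: Mapping,
                  fine: GroupingScheme) -> dict:
    """Map a coarser scheme's level estimates onto a finer scheme's
    levels (each fine level inherits from the coarse level containing
    its lines)."""
    start = {}
    for level in fine.levels:
        line = next(iter(fine.lines_in(level)))
        start[level] = estimates[coarse.level_of[line]]
    return start


def fit_schemes(data: Dataset, trait: str, family: str,
                covariance: CovarianceSpec,
                schemes: Mapping[str, GroupingScheme] | None = None,
                control: FitControl | None = None) -> dict:
    """Fit all grouping hypotheses for one trait with warm-start cascade.

    Returns ``{scheme_name: FitResult}``.  Non-converged fits are kept but
    logged; an error is raised only if every fit failed to converge.
    """
    control = control or FitControl()
    if schemes is None:
        schemes = all_schemes(list(data.lines.values()))
    fits: dict[str, FitResult] = {}
    for name in _FIT_ORDER:
        if name not in schemes:
            continue
        scheme = schemes[name]
        spec = ModelSpec(trait=trait, family=family, scheme=scheme,
                         covariance=covariance)
        candidates = [None]  # data-driven start
        for prev_name, prev in fits.items():
            if is_coarsening(schemes[prev_name], scheme):
                candidates.append(
                    _expand_start(schemes[prev_name], prev.estimates,
                                  scheme))
        best = None
        for init in candidates:
            fit = fit_gnls(spec, data, init=init, control=control)
            if best is None or fit.loglik > best.loglik + 1e-9:
                best = fit
        fits[name] = best
        logger.info("%s %s: logL=%.3f converged=%s iter=%d |grad|=%.2e",
                    trait, name, best.loglik, best.converged, best.n_iter,
                    best.grad_norm)
    if fits and not any(f.converged for f in fits.values()):
        raise RuntimeError(f"trait {trait!r}: no grouping hypothesis "
                           "converged")
    return fits


def _allocation_rows(config: AnalysisConfig, best_fits: Mapping) -> list:
    """Derived statistics where the best model distinguishes the two
    maternal seed-size classes (levels named 'large'/'small')."""
    rows = []
    classes = set(config.seed_weights)

    def class_fit(trait):
        fit = best_fits.get(trait)
        if fit is not None and classes <= set(fit.estimates):
            return fit
        return None

    for trait, organ in (("PRL", "primary root"),
                         ("AvBRL", "basal roots")):
        fit = class_fit(trait)
        if fit is None or fit.spec.family != "gompertz":
            continue
        for cls in sorted(classes):
            rows.append((f"{organ} length per gram seed", cls,
                         allocation_per_gram(fit.estimate_of(cls, "wf"),
                                             config.seed_weights[cls]),
                         "cm/g"))
    sdl = class_fit("SDLDW")
    cdw = class_fit("CDW")
    if sdl is not None and cdw is not None:
        for cls in sorted(classes):
            rows.append(("remobilization efficiency", cls,
                         remobilization_efficiency(
                             sdl.estimate_of(cls, "wf"),
                             cdw.estimate_of(cls, "maximum")), ""))
    return rows


def run_full_analysis(data: Dataset,
                      config: AnalysisConfig | None = None
                      ) -> AnalysisReport:
    """Fit every trait in the data under all five hypotheses and compile
    the report."""
    config = config or AnalysisConfig()
    traits = data.traits
    if not traits:
        raise ValueError("dataset contains no traits")
    schemes = all_schemes(list(data.lines.values()))
    selection = {}
    estimates = {}
    best_scheme = {}
    best_fits = {}
    for trait in traits:
        family = config.trait_family.get(trait)
        if family is None:
            raise ValueError(f"no curve family configured for trait "
                             f"{trait!r}")
        covariance = config.covariance_for(trait, family)
        fits = fit_schemes(data, trait, family, covariance, schemes,
                           config.control)
        table = compare_fits(fits)
        selection[trait] = table
        winner = table["scheme"].iloc[0]
        best_scheme[trait] = winner
        best_fits[trait] = fits[winner]
        estimates[trait] = fits[winner].estimates_table()
    allocation = pd.DataFrame(
        _allocation_rows(config, best_fits),
        columns=["statistic", "class", "value", "units"])
    metadata = {
        "traits": list(traits),
        "n_obs": {t: int(best_fits[t].n_obs) for t in traits},
        "seed": config.control.seed,
        "tol": config.control.tol,
        "converged": {t: bool(best_fits[t].converged) for t in traits},
    }
    return AnalysisReport(selection=selection, estimates=estimates,
                          best_scheme=best_scheme, allocation=allocation,
                          metadata=metadata)


def render_report(report: AnalysisReport, fmt: str, outdir) -> list:
    """Write the report as files; returns the paths written.

    ``fmt``: "delimited" (one CSV per table), "structured" (single JSON)
    or "human" (markdown summary).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if fmt == "delimited":
        for trait, df in report.selection.items():
            p = outdir / f"selection_{trait}.csv"
            df.to_csv(p, index=False)
            written.append(p)
        for trait, df in report.estimates.items():
            p = outdir / f"estimates_{trait}.csv"
            df.to_csv(p, index=False)
            written.append(p)
        p = outdir / "allocation.csv"
        report.allocation.to_csv(p, index=False)
        written.append(p)
    elif fmt == "structured":
        p = outdir / "report.json"
        p.write_text(report.to_json())
        written.append(p)
    elif fmt == "human":
        lines = ["# Growth model selection report", ""]
        for trait, df in report.selection.items():
            lines.append(f"## {trait} (best: {report.best_scheme[trait]})")
            lines.append(df.to_string(index=False,
                                      float_format=lambda v: f"{v:.4g}"))
            lines.append("")
            lines.append(report.estimates[trait].to_string(
                index=False, float_format=lambda v: f"{v:.4g}"))
            lines.append("")
        if len(report.allocation):
            lines.append("## Derived allocation statistics")
            lines.append(report.allocation.to_string(
                index=False, float_format=lambda v: f"{v:.4g}"))
            lines.append("")
        p = outdir / "report.md"
        p.write_text("\n".join(lines))
        written.append(p)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return written
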