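"""The comparative analysis stages, each a ModelComparison over one
dataset + tree.

Stages:

* venue screen — conventional F-test for experimental-venue effects on
  constant-condition traits (decides whether venues can be pooled);
* group comparison — log10 trait ~ risk under star and tree covariance;
* ANCOVA — log10 trait ~ risk + log10 developmental time;
* plasticity comparison — percent plasticity ~ risk;
* plasticity interaction — mass/growth plasticity ~ time plasticity x risk;
* plasticity vs mean — percent plasticity ~ log10 mean trait.

All stages that use the tree attach replicate cases as tip clusters,
count soft polytomies on the augmented tree, and subtract one residual
degree of freedom per polytomy in the tree-model coefficient tests.
Stages restricted to paired (constant + drying) cases prune the tree to
the paired species and re-derive Grafen lengths before augmenting, so
the covariance keeps unit height.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from ._version import __version__
from .pgls import (
    DegenerateFitError,
    ModelComparison,
    PglsError,
    compare_models,
    fit_gls,
)
from .traits import PLASTICITY_TRAITS, StudyCase, derive_all
from .tree import (
    PhyloTree,
    TreeError,
    attach_replicates,
    count_soft_polytomies,
    grafen_branch_lengths,
    phylo_covariance,
    prune_to_tips,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "AnalysisError",
    "MissingSpeciesError",
    "ScreenResult",
    "venue_screen",
    "compare_groups",
    "ancova_controlling_devtime",
    "compare_plasticity",
    "plasticity_interaction",
    "plasticity_vs_mean",
    "run_full_analysis",
]

MEAN_TRAITS = ("log10_dev_rate", "log10_growth_rate", "log10_mass")

#: constant-condition mean trait paired with each plasticity trait in the
#: plasticity-vs-mean regressions
DEFAULT_PLASTICITY_VS_MEAN = (
    ("dev_time", "log10_dev_rate"),
    ("mass", "log10_mass"),
    ("growth_rate", "log10_growth_rate"),
)


class AnalysisError(ValueError):
    pass


class MissingSpeciesError(AnalysisError):
    """Dataset species absent from the supplied tree."""


@dataclass(frozen=True)
class ScreenResult:
    """Joint F-test of a factor (venue) on one trait."""

    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    n_venues: int

    def to_dict(self) -> dict:
        return {
            "F": self.f_statistic,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "p": self.p_value,
            "n_venues": self.n_venues,
        }


@dataclass
class AnalysisConfig:
    """Pipeline configuration; every field has a sensible default."""

    traits: Sequence[str] = MEAN_TRAITS
    ancova_traits: Sequence[str] = ("log10_growth_rate", "log10_mass")
    plasticity_traits: Sequence[str] = PLASTICITY_TRAITS
    interaction_responses: Sequence[str] = ("mass", "growth_rate")
    plasticity_vs_mean_pairs: Sequence[Sequence[str]] = DEFAULT_PLASTICITY_VS_MEAN
    run_venue_screen: bool = True
    epsilon: Optional[float] = None  # replicate branch length; default 1e-6 x height
    min_paired_per_group: int = 3
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["traits"] = list(self.traits)
        d["ancova_traits"] = list(self.ancova_traits)
        d["plasticity_traits"] = list(self.plasticity_traits)
        d["interaction_responses"] = list(self.interaction_responses)
        d["plasticity_vs_mean_pairs"] = [list(p) for p in self.plasticity_vs_mean_pairs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise AnalysisError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def sha256(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# case table and covariance assembly
# ---------------------------------------------------------------------------


def case_table(cases: Iterable[StudyCase]) -> pd.DataFrame:
    """Flatten cases into one analysis row per case with derived traits
    under constant conditions and (where paired) percent plasticity."""
    result = derive_all(cases)
    derived = {
        (cid, treatment): dt for cid, treatment, dt in result.derived
    }
    plast = {(r.case_id, r.trait): r.percent for r in result.plasticity}
    rows = []
    for case in cases:
        if (case.case_id, "constant") not in derived:
            continue
        dt = derived[(case.case_id, "constant")]
        row = {
            "case_id": case.case_id,
            "species": case.species,
            "risk_group": case.risk_group,
            "venue": case.venue,
            "log10_dev_rate": dt.log10_dev_rate,
            "log10_growth_rate": dt.log10_growth_rate,
            "log10_mass": dt.log10_mass,
            "log10_dev_time": math.log10(case.constant.period_mean),
            "paired": case.drying is not None,
        }
        for trait in ("dev_time", "dev_rate", "growth_rate", "mass"):
            row[f"plast_{trait}"] = plast.get((case.case_id, trait), np.nan)
        rows.append(row)
    if not rows:
        raise AnalysisError("no usable cases (all lack constant-condition summaries)")
    return pd.DataFrame(rows)


def _check_species(table: pd.DataFrame, tree: PhyloTree) -> None:
    missing = sorted(set(table["species"]) - set(tree.tip_labels()))
    if missing:
        raise MissingSpeciesError(
            f"species in dataset but not in tree: {', '.join(missing)}"
        )


def tree_covariance_for(
    table: pd.DataFrame,
    tree: PhyloTree,
    epsilon: Optional[float] = None,
) -> tuple[np.ndarray, int]:
    """Case-level Brownian covariance aligned with the table rows.

    Prunes the tree to the species present, re-derives Grafen lengths on
    the pruned tree, attaches the table's cases as replicate tips, and
    returns (V, n_soft_polytomies) for the augmented tree.
    """
    _check_species(table, tree)
    species = sorted(set(table["species"]))
    if len(species) < 2:
        raise AnalysisError("need at least 2 species for a phylogenetic fit")
    sub = grafen_branch_lengths(prune_to_tips(tree, species))
    case_map = {
        sp: list(table.loc[table["species"] == sp, "case_id"])
        for sp in species
    }
    aug, report = attach_replicates(sub, case_map, epsilon=epsilon)
    cov = phylo_covariance(aug).reorder(list(table["case_id"]))
    return cov.values, report.n_soft_polytomies


def _risk_design(
    table: pd.DataFrame, covariates: Sequence[str] = (), interaction_with: Optional[str] = None
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(table))]
    names = ["intercept"]
    risk = (table["risk_group"] == "High").to_numpy(dtype=float)
    cols.append(risk)
    names.append("risk[High]")
    for cov in covariates:
        cols.append(table[cov].to_numpy(dtype=float))
        names.append(cov)
    if interaction_with is not None:
        x = table[interaction_with].to_numpy(dtype=float)
        cols.append(x * risk)
        names.append(f"{interaction_with}:risk[High]")
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def venue_screen(
    cases: Iterable[StudyCase],
    tree: Optional[PhyloTree] = None,
    trait: str = "log10_dev_rate",
) -> Optional[ScreenResult]:
    """Conventional (star) F-test of the venue factor on one
    constant-condition trait.  Returns None (stage skipped) when only one
    venue is represented.  The tree argument is accepted for interface
    symmetry; the screen is a conventional preliminary analysis and does
    not use it."""
    table = case_table(cases)
    venues = sorted(table["venue"].unique())
    if len(venues) < 2:
        logger.info("venue screen skipped: single venue %r", venues[0])
        return None
    y = table[trait].to_numpy(dtype=float)
    n = len(y)
    X_null = np.ones((n, 1))
    dummies = [
        (table["venue"] == v).to_numpy(dtype=float) for v in venues[1:]
    ]
    X_full = np.column_stack([np.ones(n)] + dummies)
    names = ["intercept"] + [f"venue[{v}]" for v in venues[1:]]
    fit_null = fit_gls(y, X_null, np.eye(n), ["intercept"], "star")
    fit_full = fit_gls(y, X_full, np.eye(n), names, "star")
    rss_null = fit_null.sigma2_hat * n
    rss_full = fit_full.sigma2_hat * n
    q = len(venues) - 1
    df_den = n - X_full.shape[1]
    if df_den < 1:
        raise AnalysisError("too few cases for the venue screen")
    f = ((rss_null - rss_full) / q) / (rss_full / df_den)
    p = float(stats.f.sf(f, q, df_den))
    result = ScreenResult(
        f_statistic=float(f), df_num=q, df_den=df_den, p_value=p, n_venues=len(venues)
    )
    logger.info(
        "venue screen on %s: F(%d, %d) = %.3f, p = %.4f -> venues %s",
        trait,
        q,
        df_den,
        f,
        p,
        "pooled" if p > 0.05 else "NOT pooled",
    )
    return result


def compare_groups(
    cases: Iterable[StudyCase],
    tree: PhyloTree,
    trait: str = "log10_dev_rate",
    epsilon: Optional[float] = None,
) -> ModelComparison:
    """log10 trait (constant conditions) ~ desiccation risk, under star
    and tree covariance."""
    if trait not in MEAN_TRAITS:
        raise AnalysisError(f"trait must be one of {MEAN_TRAITS}, got {trait!r}")
    table = case_table(cases)
    V, n_poly = tree_covariance_for(table, tree, epsilon)
    X, names = _risk_design(table)
    y = table[trait].to_numpy(dtype=float)
    return compare_models(y, X, V, n_poly, names, extra={"trait": trait})


def ancova_controlling_devtime(
    cases: Iterable[StudyCase],
    tree: PhyloTree,
    trait: str = "log10_mass",
    epsilon: Optional[float] = None,
) -> ModelComparison:
    """log10 trait ~ risk + log10 developmental time (constant conditions)."""
    if trait not in ("log10_growth_rate", "log10_mass"):
        raise AnalysisError(
            f"ANCOVA trait must be log10_growth_rate or log10_mass, got {trait!r}"
        )
    table = case_table(cases)
    V, n_poly = tree_covariance_for(table, tree, epsilon)
    X, names = _risk_design(table, covariates=["log10_dev_time"])
    y = table[trait].to_numpy(dtype=float)
    return compare_models(y, X, V, n_poly, names, extra={"trait": trait})


def _paired_table(
    cases: Iterable[StudyCase], min_per_group: int
) -> Optional[pd.DataFrame]:
    table = case_table(cases)
    paired = table[table["paired"]].reset_index(drop=True)
    counts = paired["risk_group"].value_counts()
    if counts.get("High", 0) < min_per_group or counts.get("Low", 0) < min_per_group:
        logger.info(
            "plasticity stage skipped: paired cases per group %s below minimum %d",
            counts.to_dict(),
            min_per_group,
        )
        return None
    return paired


def compare_plasticity(
    cases: Iterable[StudyCase],
    tree: PhyloTree,
    trait: str = "dev_time",
    epsilon: Optional[float] = None,
    min_per_group: int = 3,
) -> Optional[ModelComparison]:
    """Percent plasticity of one trait ~ risk, paired cases only; returns
    None (skip) when either group has too few paired cases."""
    paired = _paired_table(cases, min_per_group)
    if paired is None:
        return None
    V, n_poly = tree_covariance_for(paired, tree, epsilon)
    X, names = _risk_design(paired)
    y = paired[f"plast_{trait}"].to_numpy(dtype=float)
    return compare_models(y, X, V, n_poly, names, extra={"trait": f"plast_{trait}"})


def plasticity_interaction(
    cases: Iterable[StudyCase],
    tree: PhyloTree,
    response: str = "mass",
    epsilon: Optional[float] = None,
    min_per_group: int = 3,
) -> Optional[ModelComparison]:
    """Mass or growth plasticity ~ time plasticity x risk.  The extra
    payload carries per-group slopes for reaction-norm style output.
    Skips (None) when a group is missing or has too few paired cases."""
    if response not in ("mass", "growth_rate"):
        raise AnalysisError(f"response must be mass or growth_rate, got {response!r}")
    paired = _paired_table(cases, min_per_group)
    if paired is None:
        return None
    V, n_poly = tree_covariance_for(paired, tree, epsilon)
    X, names = _risk_design(
        paired, covariates=["plast_dev_time"], interaction_with="plast_dev_time"
    )
    y = paired[f"plast_{response}"].to_numpy(dtype=float)
    mc = compare_models(y, X, V, n_poly, names, extra={"trait": f"plast_{response}"})
    best = mc.fits[mc.best]
    i_slope = names.index("plast_dev_time")
    i_inter = names.index("plast_dev_time:risk[High]")
    slope_low = float(best.coefficients[i_slope])
    mc.extra["slopes_by_group"] = {
        "Low": slope_low,
        "High": slope_low + float(best.coefficients[i_inter]),
    }
    mc.extra["interaction_coef"] = "plast_dev_time:risk[High]"
    return mc


def plasticity_vs_mean(
    cases: Iterable[StudyCase],
    tree: PhyloTree,
    plasticity_trait: str = "dev_time",
    mean_trait: str = "log10_dev_rate",
    epsilon: Optional[float] = None,
    min_per_group: int = 3,
) -> Optional[ModelComparison]:
    """Percent plasticity ~ log10 mean trait under constant conditions."""
    if mean_trait not in MEAN_TRAITS:
        raise AnalysisError(f"mean_trait must be one of {MEAN_TRAITS}")
    paired = _paired_table(cases, min_per_group)
    if paired is None:
        return None
    V, n_poly = tree_covariance_for(paired, tree, epsilon)
    x = paired[mean_trait].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(paired)), x])
    names = ["intercept", mean_trait]
    y = paired[f"plast_{plasticity_trait}"].to_numpy(dtype=float)
    return compare_models(
        y, X, V, n_poly, names,
        extra={"trait": f"plast_{plasticity_trait}", "predictor": mean_trait},
    )


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def _stage_entry(result) -> dict:
    if result is None:
        return {"status": "skipped", "reason": "preconditions not met (see log)"}
    payload = result.to_dict()
    return {"status": "ok", "result": payload}


def run_full_analysis(
    config: AnalysisConfig,
    cases: Sequence[StudyCase],
    tree: PhyloTree,
    out_dir: Optional[Union[str, Path]] = None,
) -> dict:
    """Run every configured stage; stage failures are recorded and do not
    abort independent stages.  Deterministic given config + dataset (no
    timestamps are embedded), so repeated runs are byte-identical."""
    derive = derive_all(cases)
    stages: dict[str, dict] = {}

    def run(name: str, fn, *args, **kwargs) -> None:
        try:
            stages[name] = _stage_entry(fn(*args, **kwargs))
        except (AnalysisError, TreeError, PglsError, DegenerateFitError) as exc:
            logger.error("stage %s failed: %s", name, exc)
            stages[name] = {"status": "failed", "reason": str(exc)}

    if config.run_venue_screen:
        for trait in config.traits:
            run(f"venue_screen:{trait}", venue_screen, cases, tree, trait)
    for trait in config.traits:
        run(f"compare_groups:{trait}", compare_groups, cases, tree, trait, config.epsilon)
    for trait in config.ancova_traits:
        run(
            f"ancova:{trait}",
            ancova_controlling_devtime,
            cases,
            tree,
            trait,
            config.epsilon,
        )
    for trait in config.plasticity_traits:
        run(
            f"compare_plasticity:{trait}",
            compare_plasticity,
            cases,
            tree,
            trait,
            config.epsilon,
            config.min_paired_per_group,
        )
    for response in config.interaction_responses:
        run(
            f"plasticity_interaction:{response}",
            plasticity_interaction,
            cases,
            tree,
            response,
            config.epsilon,
            config.min_paired_per_group,
        )
    for plast_trait, mean_trait in config.plasticity_vs_mean_pairs:
        run(
            f"plasticity_vs_mean:{plast_trait}~{mean_trait}",
            plasticity_vs_mean,
            cases,
            tree,
            plast_trait,
            mean_trait,
            config.epsilon,
            config.min_paired_per_group,
        )

    # polytomy report on the full augmented tree (when species all resolve)
    try:
        table = case_table(cases)
        _check_species(table, tree)
        species = sorted(set(table["species"]))
        sub = grafen_branch_lengths(prune_to_tips(tree, species))
        case_map = {
            sp: list(table.loc[table["species"] == sp, "case_id"]) for sp in species
        }
        _, poly_report = attach_replicates(sub, case_map, epsilon=config.epsilon)
        polytomies = poly_report.to_dict()
    except (AnalysisError, TreeError) as exc:
        logger.error("polytomy report unavailable: %s", exc)
        polytomies = {"error": str(exc)}

    table = case_table(cases)
    summary = {
        "n_cases": int(len(table)),
        "n_species": int(table["species"].nunique()),
        "cases_per_group": {
            k: int(v) for k, v in table["risk_group"].value_counts().items()
        },
        "n_paired": int(table["paired"].sum()),
        "rejected_cases": [list(r) for r in derive.rejected],
    }
    report = {
        "provenance": {
            "package": "phyloplast",
            "version": __version__,
            "config": config.to_dict(),
            "config_sha256": config.sha256(),
            "seed": config.seed,
        },
        "dataset_summary": summary,
        "polytomies": polytomies,
        "stages": stages,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        pd.DataFrame(derive.derived_rows()).to_csv(
            out / "derived_traits.tsv", sep="\t", index=False
        )
        pd.DataFrame(derive.plasticity_rows()).to_csv(
            out / "plasticity.tsv", sep="\t", index=False
        )
        model_table_rows = []
        for stage, entry in stages.items():
            if entry["status"] != "ok" or "models" not in entry.get("result", {}):
                continue
            res = entry["result"]
            for label, model in res["models"].items():
                for coef, test in model["coefficient_tests"].items():
                    model_table_rows.append(
                        {
                            "stage": stage,
                            "model": label,
                            "best": label == res["best"],
                            "coefficient": coef,
                            "estimate": model["coefficients"][coef],
                            "se": model["standard_errors"][coef],
                            "t": test["t"],
                            "df": test["df_corrected"],
                            "p": test["p"],
                            "AIC": model["AIC"],
                            "AICw": model["AICw"],
                        }
                    )
        pd.DataFrame(model_table_rows).to_csv(
            out / "model_tables.tsv", sep="\t", index=False
        )
    return report
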