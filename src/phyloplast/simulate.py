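"""Synthetic trees and study-case datasets with known ground truth.

The generator mirrors the statistical structure the analysis stages
assume: species-level log10 developmental rate and log10 mass evolve by
Brownian motion on a pure-birth tree (with optional High/Low habitat
shifts), cases observe species values with measurement noise, and paired
constant/drying treatments carry group-dependent percent plasticity in
which mass (and hence growth) plasticity tracks time plasticity through a
per-group slope.  Every latent quantity is recorded in a truth record so
recovery tests can score estimates against it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .tree import Node, PhyloTree, grafen_branch_lengths, phylo_covariance
from .traits import StudyCase, TreatmentSummary

logger = logging.getLogger(__name__)

__all__ = ["SimParams", "simulate_tree", "simulate_bm_traits", "simulate_dataset"]


@dataclass
class SimParams:
    """Knobs of the dataset generator; defaults give a mid-sized dataset
    with phylogenetic signal and no group effects (a null configuration
    for the comparative stages)."""

    n_species: int = 30
    seed: int = 0

    # replicate structure: the first n_polytomy_species species (in tip
    # order) receive `replicates_per_polytomy_species` cases each
    n_polytomy_species: int = 0
    replicates_per_polytomy_species: int = 3

    # species-level evolution on the log10 scale
    sigma2_bm: float = 0.2
    root_log10_rate: float = -1.5  # ~32-day larval period
    root_log10_mass: float = -0.3  # ~0.5 g
    delta_log_rate: float = 0.0  # High minus Low shift
    delta_log_mass: float = 0.0
    group_assignment: str = "random"  # or "clustered-on-tree"
    p_high: float = 0.5
    cluster_flip_prob: float = 0.1

    # per-case measurement model
    case_noise_sd: float = 0.05  # log10-scale deviation of a case from its species
    cv_within: float = 0.15  # within-treatment CV -> sd columns
    n_per_treatment: int = 10
    prop_paired: float = 1.0  # fraction of cases given a drying treatment

    # plasticity model (percent scale, High/Low keyed)
    time_plast_mean: dict = field(default_factory=lambda: {"High": -30.0, "Low": -15.0})
    time_plast_sd: dict = field(default_factory=lambda: {"High": 10.0, "Low": 10.0})
    mass_plast_slope: dict = field(default_factory=lambda: {"High": 0.0, "Low": 0.0})
    mass_plast_intercept: dict = field(default_factory=lambda: {"High": -10.0, "Low": -10.0})
    mass_plast_sd: dict = field(default_factory=lambda: {"High": 5.0, "Low": 5.0})

    # venues: assignment probabilities and optional log10 trait offsets
    venue_probs: dict = field(
        default_factory=lambda: {"laboratory": 0.6, "mesocosm": 0.3, "field": 0.1}
    )
    venue_effect_log10: dict = field(
        default_factory=lambda: {"laboratory": 0.0, "mesocosm": 0.0, "field": 0.0}
    )

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise ValueError("n_species must be >= 4")
        if self.sigma2_bm < 0 or self.case_noise_sd < 0 or self.cv_within < 0:
            raise ValueError("variances must be >= 0")
        if self.group_assignment not in ("random", "clustered-on-tree"):
            raise ValueError(f"unknown group_assignment {self.group_assignment!r}")
        if self.n_polytomy_species > self.n_species:
            raise ValueError("n_polytomy_species cannot exceed n_species")


def simulate_tree(n_species: int, seed: Optional[int] = None,
                  rng: Optional[np.random.Generator] = None) -> PhyloTree:
    """Pure-birth topology by sequential random tip splitting, with Grafen
    branch lengths applied (ultrametric, height 1).  Deterministic given
    the seed."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if rng is None:
        rng = np.random.default_rng(seed)
    root = Node()
    tips = [root.add_child(Node()), root.add_child(Node())]
    while len(tips) < n_species:
        i = int(rng.integers(len(tips)))
        node = tips.pop(i)
        tips.append(node.add_child(Node()))
        tips.append(node.add_child(Node()))
    topo = PhyloTree.__new__(PhyloTree)  # labels assigned below, skip validate
    topo.root = root
    width = len(str(n_species))
    for i, tip in enumerate(topo.tips(), start=1):
        tip.label = f"sp{i:0{width}d}"
    topo.validate()
    return grafen_branch_lengths(topo)


def simulate_bm_traits(
    tree: PhyloTree,
    sigma2: float,
    root_state: float,
    group_effects: Optional[dict] = None,
    groups: Optional[dict] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> dict[str, float]:
    """One multivariate-normal draw of tip values under Brownian motion:
    mean root_state (+ per-tip group effect), covariance sigma2 * V(tree).

    ``group_effects`` maps group label -> additive shift and ``groups``
    maps tip label -> group label; both default to no shift.
    """
    if sigma2 < 0:
        raise ValueError(f"sigma2 must be >= 0, got {sigma2}")
    if rng is None:
        rng = np.random.default_rng(seed)
    cov = phylo_covariance(tree)
    labels = cov.labels
    mean = np.full(len(labels), float(root_state))
    if group_effects:
        if groups is None:
            raise ValueError("group_effects given without tip group assignments")
        mean += np.array([group_effects.get(groups[lbl], 0.0) for lbl in labels])
    if sigma2 == 0:
        values = mean
    else:
        # jittered Cholesky keeps replicate-cluster matrices factorable
        V = sigma2 * cov.values
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            V = V + 1e-12 * np.trace(V) / len(labels) * np.eye(len(labels))
            L = np.linalg.cholesky(V)
        values = mean + L @ rng.standard_normal(len(labels))
    return {lbl: float(v) for lbl, v in zip(labels, values)}


def _assign_groups(tree: PhyloTree, params: SimParams, rng: np.random.Generator) -> dict[str, str]:
    labels = tree.tip_labels()
    if params.group_assignment == "random":
        for _ in range(100):
            draw = rng.random(len(labels)) < params.p_high
            if 0 < draw.sum() < len(labels):
                return {lbl: ("High" if d else "Low") for lbl, d in zip(labels, draw)}
        raise RuntimeError("failed to draw two non-empty groups")
    # clustered-on-tree: two-state Markov walk from the root with a small
    # per-edge flip probability, so risk is phylogenetically structured
    flip = params.cluster_flip_prob
    for _ in range(100):
        states: dict[int, str] = {id(tree.root): "Low" if rng.random() < 0.5 else "High"}
        for node in tree.preorder():
            for child in node.children:
                s = states[id(node)]
                if rng.random() < flip:
                    s = "High" if s == "Low" else "Low"
                states[id(child)] = s
        assignment = {t.label: states[id(t)] for t in tree.tips()}
        values = set(assignment.values())
        if len(values) == 2:
            return assignment
        flip = min(0.5, flip * 1.5)
    raise RuntimeError("failed to draw two non-empty groups on the tree")


def _truncated_pct(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Percent-change draw bounded below at -100 (traits stay positive);
    out-of-range draws are resampled and logged."""
    for attempt in range(1000):
        pct = float(rng.normal(mean, sd))
        if pct > -100.0:
            if attempt:
                logger.info("plasticity draw <= -100%%; resampled %d time(s)", attempt)
            return pct
    raise RuntimeError("plasticity distribution places too much mass below -100%")


def simulate_dataset(params: SimParams) -> tuple[PhyloTree, list[StudyCase], dict]:
    """Generate (tree, cases, truth) under the documented generative model.

    The truth record stores the seed, group map, species latent values,
    per-case latent summaries and plasticity draws, and the identities of
    replicate (polytomy) species.
    """
    rng = np.random.default_rng(params.seed)
    tree = simulate_tree(params.n_species, rng=rng)
    groups = _assign_groups(tree, params, rng)
    latent_rate = simulate_bm_traits(
        tree,
        params.sigma2_bm,
        params.root_log10_rate,
        group_effects={"High": params.delta_log_rate, "Low": 0.0},
        groups=groups,
        rng=rng,
    )
    latent_mass = simulate_bm_traits(
        tree,
        params.sigma2_bm,
        params.root_log10_mass,
        group_effects={"High": params.delta_log_mass, "Low": 0.0},
        groups=groups,
        rng=rng,
    )

    species = tree.tip_labels()
    polytomy_species = species[: params.n_polytomy_species]
    venues = list(params.venue_probs)
    venue_p = np.array([params.venue_probs[v] for v in venues], dtype=float)
    venue_p = venue_p / venue_p.sum()

    cases: list[StudyCase] = []
    truth_cases: dict[str, dict] = {}
    counter = 0
    for sp in species:
        k = (
            params.replicates_per_polytomy_species
            if sp in polytomy_species
            else 1
        )
        for _ in range(k):
            counter += 1
            case_id = f"c{counter:03d}"
            venue = venues[int(rng.choice(len(venues), p=venue_p))]
            v_off = params.venue_effect_log10.get(venue, 0.0)
            lr = latent_rate[sp] + float(rng.normal(0.0, params.case_noise_sd)) + v_off
            lm = latent_mass[sp] + float(rng.normal(0.0, params.case_noise_sd)) + v_off
            period_c = 10.0 ** (-lr)
            mass_c = 10.0 ** lm
            constant = TreatmentSummary(
                period_mean=period_c,
                period_sd=params.cv_within * period_c,
                period_n=params.n_per_treatment,
                mass_mean=mass_c,
                mass_sd=params.cv_within * mass_c,
                mass_n=params.n_per_treatment,
            )
            drying = None
            plast = None
            g = groups[sp]
            if rng.random() < params.prop_paired:
                pt = _truncated_pct(
                    params.time_plast_mean[g], params.time_plast_sd[g], rng
                )
                pm_mean = (
                    params.mass_plast_intercept[g]
                    + params.mass_plast_slope[g] * pt
                )
                pm = (
                    pm_mean
                    if params.mass_plast_sd[g] == 0
                    else _truncated_pct(pm_mean, params.mass_plast_sd[g], rng)
                )
                if pm <= -100.0:
                    pm = _truncated_pct(pm_mean, params.mass_plast_sd[g], rng)
                period_d = period_c * (1.0 + pt / 100.0)
                mass_d = mass_c * (1.0 + pm / 100.0)
                drying = TreatmentSummary(
                    period_mean=period_d,
                    period_sd=params.cv_within * period_d,
                    period_n=params.n_per_treatment,
                    mass_mean=mass_d,
                    mass_sd=params.cv_within * mass_d,
                    mass_n=params.n_per_treatment,
                )
                plast = {"time_percent": pt, "mass_percent": pm}
            cases.append(
                StudyCase(
                    case_id=case_id,
                    species=sp,
                    risk_group=g,
                    venue=venue,
                    constant=constant,
                    drying=drying,
                )
            )
            truth_cases[case_id] = {
                "species": sp,
                "risk_group": g,
                "venue": venue,
                "log10_rate_case": lr,
                "log10_mass_case": lm,
                "plasticity": plast,
            }

    truth = {
        "params": asdict(params),
        "groups": groups,
        "latent_log10_rate": latent_rate,
        "latent_log10_mass": latent_mass,
        "polytomy_species": polytomy_species,
        "n_injected_polytomies": sum(
            1
            for sp in polytomy_species
            if params.replicates_per_polytomy_species > 2
        ),
        "cases": truth_cases,
    }
    return tree, cases, truth
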