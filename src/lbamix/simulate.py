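"""Synthetic-data generation: homogeneous, profile-heterogeneous and
multigene alignments with recorded ground truth, plus the heterogeneity
calibration used to pick the synthetic profile sharpness."""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from .trees_io import (
    Alignment,
    BlmfSpec,
    Tree,
    apply_blmf,
    load_fixture_tree,
    write_alignment,
    write_newick,
)
from .substitution_models import (
    ExchangeabilityMatrix,
    FrequencyProfile,
    ProfileMixture,
    RatesAcrossSites,
    SpectralDecomposition,
    SubstitutionModel,
    build_rate_matrix,
    discrete_gamma_rates,
    get_default_frequencies,
    sample_profile_mixture,
)

SMALL_N_SITES = 7_743
LARGE_N_SITES = 30_942
GENE_N_SITES = 1_548

__all__ = [
    "SMALL_N_SITES",
    "LARGE_N_SITES",
    "GENE_N_SITES",
    "SimulationConfig",
    "CalibrationError",
    "CalibrationReport",
    "simulate_alignment",
    "simulate_multigene",
    "calibrate_heterogeneity",
    "make_benchmark_suite",
]


@dataclass
class SimulationConfig:
    name: str
    tree_fixture: str
    blmf: BlmfSpec
    model: SubstitutionModel
    n_sites: int = SMALL_N_SITES
    n_replicates: int = 100
    base_seed: int = 0
    model_class: str = "homogeneous"

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")

    def replicate_seed(self, index: int) -> int:
        return self.base_seed + index

    def tree(self) -> Tree:
        return apply_blmf(load_fixture_tree(self.tree_fixture), self.blmf)


def _sample_descendants(
    parent_states: np.ndarray, P: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(parent_states.shape[0])
    return np.clip((u[:, None] > cum[parent_states]).sum(axis=1), 0, 19).astype(np.uint8)


def simulate_alignment(
    tree: Tree,
    model: SubstitutionModel,
    n_sites: int,
    rng: np.random.Generator,
) -> Alignment:
    """Simulate i.i.d. sites: component drawn by mixture weight, rate class
    uniformly, root state from the component profile, then evolution along
    each branch with expm(Q_k * rate * length)."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    mix, rates = model.mixture, model.rates
    comp = rng.choice(mix.k, size=n_sites, p=mix.weights)
    rate_idx = rng.choice(rates.ncat, size=n_sites, p=rates.probs)

    taxa = tree.leaf_names
    row = {name: i for i, name in enumerate(taxa)}
    codes = np.empty((len(taxa), n_sites), dtype=np.uint8)

    spectrals: dict[int, SpectralDecomposition] = {}
    for k in np.unique(comp):
        pi = mix.profiles[k].smoothed().freqs
        Q = build_rate_matrix(model.exchangeabilities, FrequencyProfile(pi))
        spectrals[int(k)] = SpectralDecomposition(Q, pi)

    nodes = list(tree.preorder())
    for k in np.unique(comp):
        sp = spectrals[int(k)]
        for g in range(rates.ncat):
            idx = np.flatnonzero((comp == k) & (rate_idx == g))
            if idx.size == 0:
                continue
            states: dict[int, np.ndarray] = {}
            states[id(nodes[0])] = rng.choice(20, size=idx.size, p=sp.pi).astype(np.uint8)
            for node in nodes:
                if node.parent is None:
                    continue
                P = sp.transition(node.length * rates.rates[g])
                states[id(node)] = _sample_descendants(states[id(node.parent)], P, rng)
            for node in nodes:
                if node.is_leaf:
                    codes[row[node.name], idx] = states[id(node)]
    return Alignment(taxa, codes, site_truth={"component": comp, "rate": rate_idx})


def simulate_multigene(
    tree: Tree,
    gene_specs: list[tuple[ExchangeabilityMatrix, ProfileMixture, int]],
    rng: np.random.Generator,
    rates: RatesAcrossSites | None = None,
) -> tuple[Alignment, list[tuple[int, int]]]:
    """Concatenation of per-gene simulations; returns the alignment and the
    half-open 0-based site range of each gene."""
    if not gene_specs:
        raise ValueError("at least one gene spec is required")
    rates = rates or discrete_gamma_rates(0.6, 4)
    blocks, ranges, start = [], [], 0
    truth_comp, truth_rate = [], []
    for exch, mixture, n_sites in gene_specs:
        model = SubstitutionModel(exch, mixture, rates, name=f"{exch.name}-mix")
        aln = simulate_alignment(tree, model, n_sites, rng)
        blocks.append(aln.codes)
        truth_comp.append(aln.site_truth["component"])
        truth_rate.append(aln.site_truth["rate"])
        ranges.append((start, start + n_sites))
        start += n_sites
    taxa = tree.leaf_names
    combined = Alignment(
        taxa,
        np.concatenate(blocks, axis=1),
        site_truth={
            "component": np.concatenate(truth_comp),
            "rate": np.concatenate(truth_rate),
        },
    )
    return combined, ranges


# ---------------------------------------------------------------------------
# Heterogeneity calibration


class CalibrationError(RuntimeError):
    def __init__(self, message: str, report: "CalibrationReport"):
        super().__init__(message)
        self.report = report


@dataclass
class CalibrationReport:
    sharpness_grid: list[float]
    pilot_z: list[float]
    chosen_sharpness: float | None
    target_range: tuple[float, float]
    n_sites: int
    n_pilot: int
    seed: int


def calibrate_heterogeneity(
    tree: Tree,
    R: ExchangeabilityMatrix,
    sharpness_grid: list[float],
    K: int,
    target_z: tuple[float, float],
    rng: np.random.Generator,
    n_sites: int = 2_000,
    n_pilot: int = 2,
    pb_replicates: int = 30,
    weight_conc: float = 1.0,
    alpha: float = 0.6,
    ncat: int = 4,
) -> tuple[ProfileMixture, CalibrationReport]:
    """Pick the profile sharpness whose simulated data give a homogeneous-fit
    amino-acid-diversity Z inside ``target_z`` (pilot parametric bootstrap).

    The grid is scanned in the given order; the first sharpness whose mean
    pilot Z falls inside the range wins.  Z grows as sharpness shrinks, so
    pass the grid in decreasing-sharpness order.
    """
    from .likelihood_ml import FitOptions, fit_model, parametric_bootstrap_zscore

    lo, hi = target_z
    if lo <= 2:
        raise ValueError("target Z lower bound must exceed the adequacy cutoff 2")
    seed = int(rng.integers(2**31 - 1))
    master = np.random.default_rng(seed)
    base = FrequencyProfile(get_default_frequencies(R.name))
    rates = discrete_gamma_rates(alpha, ncat)
    pilot_z: list[float] = []
    chosen: float | None = None
    chosen_mix: ProfileMixture | None = None
    for sharpness in sharpness_grid:
        sub = np.random.default_rng(master.integers(2**31 - 1))
        mixture = sample_profile_mixture(K, base, sharpness, weight_conc, sub)
        model = SubstitutionModel(R, mixture, rates, name=f"{R.name}-synthetic")
        zs = []
        for _ in range(n_pilot):
            aln = simulate_alignment(tree, model, n_sites, sub)
            fit = fit_model(
                aln,
                tree,
                SubstitutionModel.homogeneous(R, alpha=alpha, ncat=ncat),
                FitOptions(estimate_frequencies=True, n_restarts=1),
            )
            res = parametric_bootstrap_zscore(fit, n_replicates=pb_replicates, rng=sub)
            zs.append(res.z_score)
        pilot_z.append(float(np.mean(zs)))
        if chosen is None and lo < pilot_z[-1] < hi:
            chosen, chosen_mix = sharpness, mixture
    report = CalibrationReport(
        list(sharpness_grid), pilot_z, chosen, (lo, hi), n_sites, n_pilot, seed
    )
    if chosen_mix is None:
        raise CalibrationError(
            f"no sharpness in the grid reached Z in ({lo}, {hi}); pilot Z = {pilot_z}",
            report,
        )
    return chosen_mix, report


# ---------------------------------------------------------------------------
# On-disk dataset batches


def make_benchmark_suite(
    configs: list[SimulationConfig], out_dir: str, force: bool = False
) -> str:
    """Write {condition}/{replicate}.fasta + truth.yaml plus a manifest TSV.

    Returns the manifest path.  Refuses to write into an existing non-empty
    directory unless ``force``.
    """
    if os.path.isdir(out_dir) and os.listdir(out_dir) and not force:
        raise FileExistsError(f"output directory {out_dir!r} is not empty (use force)")
    os.makedirs(out_dir, exist_ok=True)
    rows = ["condition\treplicate\tpath\tseed\ttree\tblmf\tmodel_class"]
    for cfg in configs:
        cond_dir = os.path.join(out_dir, cfg.name)
        os.makedirs(cond_dir, exist_ok=True)
        tree = cfg.tree()
        with open(os.path.join(cond_dir, "tree.nwk"), "w") as fh:
            fh.write(write_newick(tree) + "\n")
        for rep in range(cfg.n_replicates):
            seed = cfg.replicate_seed(rep)
            rng = np.random.default_rng(seed)
            aln = simulate_alignment(tree, cfg.model, cfg.n_sites, rng)
            rel = os.path.join(cfg.name, f"{rep:03d}.fasta")
            write_alignment(aln, os.path.join(out_dir, rel), "fasta")
            truth = {
                "condition": cfg.name,
                "replicate": rep,
                "seed": seed,
                "tree_fixture": cfg.tree_fixture,
                "blmf": {"factor": cfg.blmf.factor, "target_tags": list(cfg.blmf.target_tags)},
                "model_class": cfg.model_class,
                "n_sites": cfg.n_sites,
            }
            with open(os.path.join(cond_dir, f"{rep:03d}.truth.yaml"), "w") as fh:
                yaml.safe_dump(truth, fh)
            rows.append(
                f"{cfg.name}\t{rep}\t{rel}\t{seed}\t{cfg.tree_fixture}"
                f"\t{cfg.blmf.factor:g}\t{cfg.model_class}"
            )
    manifest = os.path.join(out_dir, "manifest.tsv")
    with open(manifest, "w") as fh:
        fh.write("\n".join(rows) + "\n")
    return manifest
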