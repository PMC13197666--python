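"""Maximum-likelihood engine: pruning likelihoods for homogeneous, finite
profile-mixture and partitioned models, bounded quasi-Newton + EM fitting,
BIC selection, focal-split topology calls with RELL bootstrap support, and
parametric-bootstrap model adequacy."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from ._pruning import (
    TreeArrays,
    compress_patterns,
    mixture_loglik_and_grad,
    mixture_site_loglik,
)
from .trees_io import Alignment, Tree
from .substitution_models import (
    ExchangeabilityMatrix,
    FrequencyProfile,
    ProfileMixture,
    SpectralDecomposition,
    SubstitutionModel,
    build_rate_matrix,
    discrete_gamma_rates,
    get_cxx_mixture,
    get_exchangeability,
    smooth_profile,
)
from .benchmark import AdequacyResult, UndefinedZError, aa_diversity

BL_BOUNDS = (1e-8, 50.0)
ALPHA_BOUNDS = (0.02, 100.0)

__all__ = [
    "FitOptions",
    "MlFit",
    "TopologyCall",
    "PartitionedModel",
    "observed_frequencies",
    "site_log_likelihoods",
    "fit_model",
    "fit_partitioned",
    "bic_score",
    "bic_select",
    "mlho_candidates",
    "select_mlhe",
    "rell_support",
    "evaluate_focal_split",
    "parametric_bootstrap_zscore",
]


@dataclass(frozen=True)
class FitOptions:
    estimate_frequencies: bool = False  # '+F': observed counts replace the F profile
    estimate_weights: bool = False  # EM over mixture weights
    optimize_branch_lengths: bool = True
    optimize_alpha: bool = True
    n_restarts: int = 1
    seed: int = 0
    max_outer: int = 6
    tol: float = 1e-6
    max_lbfgs_iter: int = 200


@dataclass
class PartitionedModel:
    """Hard site-range partitioning; edge-linked branch lengths with
    per-partition rate multipliers (first partition's multiplier fixed at 1)."""

    ranges: list[tuple[int, int]]
    models: list[SubstitutionModel]

    def __post_init__(self):
        if len(self.ranges) != len(self.models) or not self.models:
            raise ValueError("ranges and models must align and be non-empty")
        pos = 0
        for start, stop in self.ranges:
            if start != pos or stop <= start:
                raise ValueError("partition ranges must be disjoint, ordered, covering")
            pos = stop


@dataclass
class MlFit:
    name: str
    model: SubstitutionModel | PartitionedModel
    tree: Tree
    alpha: float | list[float]
    weights: np.ndarray | None
    frequencies: np.ndarray | None
    log_likelihood: float
    n_parameters: int
    site_log_likelihoods: np.ndarray
    converged: bool
    taxa: list[str]
    n_sites: int
    observed_diversity: float
    rate_multipliers: list[float] | None = None


@dataclass
class TopologyCall:
    best_label: str
    support: float | None  # percent in [0, 100]; None when no bootstrap run
    log_likelihoods: dict[str, float]
    support_method: str = "bootstrap (RELL)"
    fits: dict[str, MlFit] | None = None


def observed_frequencies(aln: Alignment) -> np.ndarray:
    counts = np.bincount(aln.codes[aln.codes < 20].ravel(), minlength=20).astype(float)
    return smooth_profile(counts / max(counts.sum(), 1.0))


def _spectrals(model: SubstitutionModel) -> list[SpectralDecomposition]:
    out = []
    for prof in model.mixture.profiles:
        pi = smooth_profile(prof.freqs)
        Q = build_rate_matrix(model.exchangeabilities, FrequencyProfile(pi))
        out.append(SpectralDecomposition(Q, pi))
    return out


def _apply_plus_f(model: SubstitutionModel, freqs: np.ndarray) -> SubstitutionModel:
    """Swap the observed-frequency profile into the model: the single profile
    for a homogeneous model, else the component labeled 'F'."""
    mix = model.mixture
    prof = FrequencyProfile(smooth_profile(freqs))
    if mix.k == 1:
        return replace(model, mixture=ProfileMixture.single(prof, label="F"))
    if mix.labels is None or "F" not in mix.labels:
        raise ValueError("mixture has no 'F' component to receive observed frequencies")
    idx = mix.labels.index("F")
    profiles = list(mix.profiles)
    profiles[idx] = prof
    return replace(model, mixture=ProfileMixture(tuple(profiles), mix.weights, mix.labels))


def site_log_likelihoods(
    aln: Alignment, tree: Tree, model: SubstitutionModel | PartitionedModel
) -> np.ndarray:
    """Per-site log-likelihoods; their sum is the total log-likelihood."""
    if isinstance(model, PartitionedModel):
        out = np.empty(aln.n_sites)
        for (start, stop), sub in zip(model.ranges, model.models):
            out[start:stop] = site_log_likelihoods(
                aln.subset_sites(np.arange(start, stop)), tree, sub
            )
        return out
    missing = set(aln.taxa) - set(tree.leaf_names)
    if missing:
        raise KeyError(f"alignment taxa absent from tree: {sorted(missing)}")
    tarr = TreeArrays.from_tree(tree, aln.taxa)
    patterns, inverse, _ = compress_patterns(aln)
    comp = mixture_site_loglik(
        tarr, patterns, _spectrals(model), model.rates.rates, model.rates.probs
    )
    logw = np.log(np.maximum(model.mixture.weights, 1e-300))
    return logsumexp(logw[:, None] + comp, axis=0)[inverse]


# ---------------------------------------------------------------------------
# Fitting


def _em_weights(
    comp_ll: np.ndarray, counts: np.ndarray, w0: np.ndarray, tol: float = 1e-8
) -> tuple[np.ndarray, float]:
    """EM on mixture weights given a (K, P) component log-likelihood matrix.
    Each sweep is the responsibility-weighted simplex update; lnL is monotone."""
    w = w0.copy()
    n = counts.sum()
    prev = -np.inf
    for _ in range(500):
        logw = np.log(np.maximum(w, 1e-300))
        joint = logw[:, None] + comp_ll
        tot = logsumexp(joint, axis=0)
        lnl = float(tot @ counts)
        resp = np.exp(joint - tot[None, :])
        w = (resp @ counts) / n
        w = np.maximum(w, 0.0)
        w /= w.sum()
        if lnl - prev < tol:
            break
        prev = lnl
    return w, lnl


def fit_model(
    aln: Alignment,
    tree: Tree,
    model: SubstitutionModel,
    options: FitOptions = FitOptions(),
) -> MlFit:
    """Optimize branch lengths and alpha (bounded L-BFGS-B on log scale, with
    seeded random restarts) interleaved with EM weight updates."""
    if options.estimate_frequencies:
        model = _apply_plus_f(model, observed_frequencies(aln))
    tarr0 = TreeArrays.from_tree(tree, aln.taxa)
    nodes = [n for n in tree.postorder()]
    patterns, inverse, counts = compress_patterns(aln)
    spectrals = _spectrals(model)
    K = model.mixture.k
    ncat = model.rates.ncat
    rate_probs = model.rates.probs

    edge_len0 = np.clip(tarr0.lengths[:-1], *BL_BOUNDS)
    theta_bl0 = np.log(edge_len0)
    n_edges = theta_bl0.size
    free_alpha = options.optimize_alpha and ncat > 1

    weights = model.mixture.weights.copy()

    Qs = [
        build_rate_matrix(model.exchangeabilities, p.smoothed())
        for p in model.mixture.profiles
    ]

    def _rates(alpha: float):
        return discrete_gamma_rates(alpha, ncat) if ncat > 1 else model.rates

    def comp_matrix(log_bl: np.ndarray, alpha: float) -> np.ndarray:
        tarr = tarr0.with_lengths(np.exp(log_bl))
        return mixture_site_loglik(tarr, patterns, spectrals, _rates(alpha).rates, rate_probs)

    def _lnl_only(log_bl: np.ndarray, alpha: float) -> float:
        comp = comp_matrix(log_bl, alpha)
        logw = np.log(np.maximum(weights, 1e-300))
        return float(logsumexp(logw[:, None] + comp, axis=0) @ counts)

    def neg_lnl_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Analytic branch-length gradient; alpha by central difference."""
        log_bl = theta[:n_edges] if options.optimize_branch_lengths else theta_bl0
        alpha = float(np.exp(theta[n_edges])) if free_alpha else model.rates.alpha
        bl = np.exp(log_bl)
        rt = _rates(alpha)
        lnl, grad_bl = mixture_loglik_and_grad(
            tarr0.with_lengths(bl), patterns, counts, spectrals, Qs,
            rt.rates, rate_probs, weights,
        )
        g = np.zeros_like(theta)
        g[:n_edges] = -(grad_bl * bl)  # chain rule through the log transform
        if free_alpha:
            h = 1e-4 * alpha
            dl = _lnl_only(log_bl, alpha + h) - _lnl_only(log_bl, alpha - h)
            g[n_edges] = -(dl / (2.0 * h)) * alpha
        return -lnl, g

    if options.optimize_branch_lengths:
        bounds = [(np.log(BL_BOUNDS[0]), np.log(BL_BOUNDS[1]))] * n_edges
    else:  # pin branch-length coordinates so only alpha is free
        bounds = [(v, v) for v in theta_bl0]
    theta0 = theta_bl0.copy()
    if free_alpha:
        theta0 = np.append(theta0, np.log(model.rates.alpha))
        bounds.append((np.log(ALPHA_BOUNDS[0]), np.log(ALPHA_BOUNDS[1])))

    rng = np.random.default_rng(options.seed)
    best = None
    converged = False
    for restart in range(max(1, options.n_restarts)):
        start = theta0 if restart == 0 else theta0 + rng.normal(0.0, 0.5, theta0.size)
        start = np.clip(start, [b[0] for b in bounds], [b[1] for b in bounds])
        theta, prev_lnl = start, -np.inf
        ok = True
        for _ in range(max(1, options.max_outer)):
            if options.optimize_branch_lengths or free_alpha:
                res = minimize(
                    neg_lnl_grad,
                    theta,
                    method="L-BFGS-B",
                    jac=True,
                    bounds=bounds,
                    options={"maxiter": options.max_lbfgs_iter, "ftol": 1e-10},
                )
                theta, ok = res.x, bool(res.success)
            log_bl = theta[:n_edges] if options.optimize_branch_lengths else theta_bl0
            alpha = float(np.exp(theta[n_edges])) if free_alpha else model.rates.alpha
            comp = comp_matrix(log_bl, alpha)
            if options.estimate_weights and K > 1:
                weights, lnl = _em_weights(comp, counts, weights)
            else:
                logw = np.log(np.maximum(weights, 1e-300))
                lnl = float(logsumexp(logw[:, None] + comp, axis=0) @ counts)
            if not (options.estimate_weights and K > 1):
                break
            if lnl - prev_lnl < options.tol:
                break
            prev_lnl = lnl
        if best is None or lnl > best[0]:
            best = (lnl, theta.copy(), weights.copy(), alpha, comp)
            converged = ok
        weights = model.mixture.weights.copy()

    lnl, theta, weights, alpha, comp = best
    log_bl = theta[:n_edges] if options.optimize_branch_lengths else theta_bl0
    fitted_tree = tree.copy()
    for node, length in zip(fitted_tree.postorder(), np.exp(log_bl)):
        node.length = float(length)

    final_model = replace(
        model,
        mixture=model.mixture.reweighted(weights),
        rates=discrete_gamma_rates(alpha, ncat) if ncat > 1 else model.rates,
    )
    logw = np.log(np.maximum(weights, 1e-300))
    site_ll = logsumexp(logw[:, None] + comp, axis=0)[inverse]

    k = 0
    if options.optimize_branch_lengths:
        k += n_edges
    if free_alpha:
        k += 1
    if options.estimate_frequencies:
        k += 19
    if options.estimate_weights and K > 1:
        k += K - 1
    return MlFit(
        name=model.name,
        model=final_model,
        tree=fitted_tree,
        alpha=alpha,
        weights=weights if options.estimate_weights else None,
        frequencies=final_model.mixture.profiles[0].freqs
        if options.estimate_frequencies
        else None,
        log_likelihood=lnl,
        n_parameters=k,
        site_log_likelihoods=site_ll,
        converged=converged,
        taxa=list(aln.taxa),
        n_sites=aln.n_sites,
        observed_diversity=aa_diversity(aln),
    )


def fit_partitioned(
    aln: Alignment,
    tree: Tree,
    partition: PartitionedModel,
    options: FitOptions = FitOptions(),
) -> MlFit:
    """Edge-linked branch lengths; per-partition rate multiplier and alpha."""
    n_part = len(partition.models)
    if partition.ranges[-1][1] != aln.n_sites:
        raise ValueError("partition ranges must cover the alignment")
    tarr0 = TreeArrays.from_tree(tree, aln.taxa)
    parts = []
    models = list(partition.models)
    for (start, stop), sub in zip(partition.ranges, models):
        sub_aln = aln.subset_sites(np.arange(start, stop))
        if options.estimate_frequencies:
            sub = _apply_plus_f(sub, observed_frequencies(sub_aln))
        patterns, inverse, counts = compress_patterns(sub_aln)
        parts.append((patterns, inverse, counts, _spectrals(sub), sub))

    n_edges = tarr0.lengths.size - 1
    theta_bl0 = np.log(np.clip(tarr0.lengths[:-1], *BL_BOUNDS))
    theta0 = np.concatenate(
        [
            theta_bl0,
            np.zeros(n_part - 1),  # log rate multipliers, partition 0 fixed at 1
            [np.log(m.rates.alpha) for m in models],
        ]
    )
    bounds = (
        [(np.log(BL_BOUNDS[0]), np.log(BL_BOUNDS[1]))] * n_edges
        + [(-5.0, 5.0)] * (n_part - 1)
        + [(np.log(ALPHA_BOUNDS[0]), np.log(ALPHA_BOUNDS[1]))] * n_part
    )

    def unpack(theta):
        log_bl = theta[:n_edges]
        mult = np.concatenate([[1.0], np.exp(theta[n_edges : n_edges + n_part - 1])])
        alphas = np.exp(theta[n_edges + n_part - 1 :])
        return log_bl, mult, alphas

    def neg_lnl(theta):
        log_bl, mult, alphas = unpack(theta)
        total = 0.0
        for p, (patterns, _, counts, spectrals, sub) in enumerate(parts):
            rates = discrete_gamma_rates(float(alphas[p]), sub.rates.ncat)
            tarr = tarr0.with_lengths(np.exp(log_bl) * mult[p])
            comp = mixture_site_loglik(tarr, patterns, spectrals, rates.rates, rates.probs)
            logw = np.log(np.maximum(sub.mixture.weights, 1e-300))
            total += float(logsumexp(logw[:, None] + comp, axis=0) @ counts)
        return -total

    res = minimize(
        neg_lnl,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": options.max_lbfgs_iter, "ftol": 1e-10},
    )
    log_bl, mult, alphas = unpack(res.x)
    fitted_tree = tree.copy()
    for node, length in zip(fitted_tree.postorder(), np.exp(log_bl)):
        node.length = float(length)

    site_ll = np.empty(aln.n_sites)
    fitted_models = []
    for p, ((start, stop), (patterns, inverse, counts, spectrals, sub)) in enumerate(
        zip(partition.ranges, parts)
    ):
        rates = discrete_gamma_rates(float(alphas[p]), sub.rates.ncat)
        tarr = tarr0.with_lengths(np.exp(log_bl) * mult[p])
        comp = mixture_site_loglik(tarr, patterns, spectrals, rates.rates, rates.probs)
        logw = np.log(np.maximum(sub.mixture.weights, 1e-300))
        site_ll[start:stop] = logsumexp(logw[:, None] + comp, axis=0)[inverse]
        fitted_models.append(replace(sub, rates=rates))

    k = n_edges + (n_part - 1) + n_part + (19 * n_part if options.estimate_frequencies else 0)
    return MlFit(
        name="Partitioned",
        model=PartitionedModel(partition.ranges, fitted_models),
        tree=fitted_tree,
        alpha=[float(a) for a in alphas],
        weights=None,
        frequencies=None,
        log_likelihood=-res.fun,
        n_parameters=k,
        site_log_likelihoods=site_ll,
        converged=bool(res.success),
        taxa=list(aln.taxa),
        n_sites=aln.n_sites,
        observed_diversity=aa_diversity(aln),
        rate_multipliers=[float(m) for m in mult],
    )


# ---------------------------------------------------------------------------
# Model selection


def bic_score(lnl: float, k: int, n: int) -> float:
    """BIC = -2 lnL + k ln(n), with n = number of alignment columns."""
    return -2.0 * lnl + k * np.log(n)


def bic_select(
    aln: Alignment,
    tree: Tree,
    candidates: list[tuple[str, SubstitutionModel, FitOptions]],
) -> tuple[MlFit, pd.DataFrame]:
    """Minimum BIC wins; ties broken by fewer parameters then candidate order."""
    if not candidates:
        raise ValueError("at least one candidate required")
    n = aln.n_sites
    rows, fits = [], []
    for idx, (name, model, opts) in enumerate(candidates):
        fit = fit_model(aln, tree, model, opts)
        bic = bic_score(fit.log_likelihood, fit.n_parameters, n)
        rows.append(
            {"model": name, "lnL": fit.log_likelihood, "k": fit.n_parameters, "BIC": bic}
        )
        fits.append(fit)
    table = pd.DataFrame(rows)
    order = sorted(
        range(len(fits)), key=lambda i: (round(rows[i]["BIC"], 9), rows[i]["k"], i)
    )
    return fits[order[0]], table


def mlho_candidates(alpha: float = 0.6, ncat: int = 4) -> list[tuple[str, SubstitutionModel, FitOptions]]:
    """Default homogeneous ML candidate panel (fixed, documented set)."""
    plain = FitOptions()
    plus_f = FitOptions(estimate_frequencies=True)
    out = []
    for name in ("POISSON", "WAG", "LG", "JTT"):
        out.append(
            (f"{name}+G", SubstitutionModel.homogeneous(name, alpha=alpha, ncat=ncat), plain)
        )
    for name in ("WAG", "LG"):
        out.append(
            (
                f"{name}+F+G",
                SubstitutionModel.homogeneous(name, alpha=alpha, ncat=ncat),
                plus_f,
            )
        )
    return out


def _wag_cxx_model(level: str, alpha: float, ncat: int) -> SubstitutionModel:
    exch = get_exchangeability("WAG")
    mix = get_cxx_mixture(level, extra_profile=FrequencyProfile(np.full(20, 0.05)))
    return SubstitutionModel(
        exch, mix, discrete_gamma_rates(alpha, ncat), name=f"WAG+F+G+{level}"
    )


def select_mlhe(
    aln: Alignment,
    tree: Tree,
    is_homogeneous_protocol: bool,
    alpha: float = 0.6,
    ncat: int = 4,
    cxx_levels: tuple[str, ...] = ("C10", "C20", "C30", "C40", "C50", "C60"),
    options: FitOptions | None = None,
) -> tuple[MlFit, str]:
    """Heterogeneous-protocol: BIC over WAG+F+G and WAG+F+G+CXX (weights
    re-estimated per candidate).  Homogeneous-protocol: fixed WAG+F+G+C60
    with estimated weights."""
    opts = options or FitOptions(estimate_frequencies=True, estimate_weights=True)
    if is_homogeneous_protocol:
        fit = fit_model(aln, tree, _wag_cxx_model("C60", alpha, ncat), opts)
        return fit, "homogeneous (fixed C60)"
    candidates: list[tuple[str, SubstitutionModel, FitOptions]] = [
        (
            "WAG+F+G",
            SubstitutionModel.homogeneous("WAG", alpha=alpha, ncat=ncat),
            FitOptions(estimate_frequencies=True),
        )
    ]
    for level in cxx_levels:
        candidates.append((f"WAG+F+G+{level}", _wag_cxx_model(level, alpha, ncat), opts))
    fit, _table = bic_select(aln, tree, candidates)
    return fit, "heterogeneous (BIC over CXX)"


# ---------------------------------------------------------------------------
# Focal-split evaluation and adequacy


def rell_support(
    site_lls: dict[str, np.ndarray],
    best: str,
    n_bootstrap: int,
    rng: np.random.Generator,
) -> float:
    """Percent of RELL bootstrap replicates in which ``best`` beats all others."""
    labels = list(site_lls)
    sll = np.stack([site_lls[lab] for lab in labels])
    n = sll.shape[1]
    counts = rng.multinomial(n, np.full(n, 1.0 / n), size=n_bootstrap)
    totals = counts @ sll.T
    best_idx = labels.index(best)
    others = [j for j in range(len(labels)) if j != best_idx]
    wins = np.all(totals[:, [best_idx]] > totals[:, others], axis=1)
    return 100.0 * float(wins.mean())


def evaluate_focal_split(
    aln: Alignment,
    candidates: dict[str, Tree],
    model: SubstitutionModel | PartitionedModel,
    options: FitOptions = FitOptions(),
    n_bootstrap: int = 100,
    rng: np.random.Generator | None = None,
    method: str = "rell",
) -> TopologyCall:
    """Fit the model on each candidate resolution; winner by lnL, support =
    percentage of bootstrap replicates in which the winner beats both others."""
    rng = rng or np.random.default_rng(0)
    fits: dict[str, MlFit] = {}
    for label, cand in candidates.items():
        if isinstance(model, PartitionedModel):
            fits[label] = fit_partitioned(aln, cand, model, options)
        else:
            fits[label] = fit_model(aln, cand, model, options)
    labels = list(fits)
    lnls = {lab: fits[lab].log_likelihood for lab in labels}
    best = max(labels, key=lambda lab: lnls[lab])

    support: float | None = None
    if n_bootstrap > 0:
        n = aln.n_sites
        if method == "rell":
            support = rell_support(
                {lab: fits[lab].site_log_likelihoods for lab in labels},
                best,
                n_bootstrap,
                rng,
            )
        elif method == "refit":
            totals = np.empty((n_bootstrap, len(labels)))
            for b in range(n_bootstrap):
                idx = rng.integers(0, n, size=n)
                baln = aln.subset_sites(idx)
                for j, lab in enumerate(labels):
                    if isinstance(model, PartitionedModel):
                        raise ValueError("full-refit bootstrap unsupported for partitions")
                    totals[b, j] = fit_model(baln, candidates[lab], model, options).log_likelihood
            best_idx = labels.index(best)
            others = [j for j in range(len(labels)) if j != best_idx]
            wins = np.all(totals[:, [best_idx]] > totals[:, others], axis=1)
            support = 100.0 * float(wins.mean())
        else:
            raise ValueError(f"unknown bootstrap method {method!r}")
    return TopologyCall(
        best_label=best,
        support=support,
        log_likelihoods=lnls,
        support_method="bootstrap (RELL)" if method == "rell" else "bootstrap (refit)",
        fits=fits,
    )


def parametric_bootstrap_zscore(
    fit: MlFit,
    n_replicates: int = 100,
    rng: np.random.Generator | None = None,
) -> AdequacyResult:
    """Simulate from the fitted model on the fitted tree; Z of the observed
    mean per-column amino-acid diversity against the replicate distribution."""
    from .simulate import simulate_alignment, simulate_multigene

    rng = rng or np.random.default_rng(0)
    reps = np.empty(n_replicates)
    for b in range(n_replicates):
        if isinstance(fit.model, PartitionedModel):
            specs = []
            for (start, stop), sub, mult in zip(
                fit.model.ranges, fit.model.models, fit.rate_multipliers
            ):
                specs.append((sub, mult, stop - start))
            blocks = []
            for sub, mult, n_sites in specs:
                scaled = fit.tree.copy()
                for node in scaled.postorder():
                    node.length *= mult
                blocks.append(simulate_alignment(scaled, sub, n_sites, rng).codes)
            sim = Alignment(fit.tree.leaf_names, np.concatenate(blocks, axis=1))
        else:
            sim = simulate_alignment(fit.tree, fit.model, fit.n_sites, rng)
        reps[b] = aa_diversity(sim)
    sd = float(reps.std(ddof=1))
    if sd == 0.0:
        raise UndefinedZError("replicate diversity has zero spread", reps)
    # sign convention: positive Z when the fitted model over-predicts diversity
    # (i.e. fails to capture sharp site profiles), as in the PPA/PB literature
    z = (float(reps.mean()) - fit.observed_diversity) / sd
    return AdequacyResult(
        z_score=float(z),
        observed=fit.observed_diversity,
        replicates=reps,
        mode="pb",
    )
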