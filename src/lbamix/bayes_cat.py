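"""Bayesian engine: GTR+G and a truncated Dirichlet-process profile-mixture
(CAT-GTR analog) sampler with occupied-category (Nmode) tracing, focal-split
posterior probabilities, posterior-predictive adequacy and convergence
diagnostics.

Sampler sketch (one cycle = one full sweep):
  allocation Gibbs over all sites (auxiliary-component style, truncation nmax)
  -> per-category profile Metropolis-Hastings (Dirichlet random-walk)
  -> exchangeability update (Dirichlet random-walk on the 190-simplex)
  -> tree-length scaling + single-branch multiplicative moves
  -> alpha move -> DP concentration move -> focal-topology move.
Rate classes are marginalized analytically (discrete Gamma, 4 categories).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from ._pruning import TreeArrays, compress_patterns, component_site_loglik
from .trees_io import Alignment, Tree, clade_branch_length
from .substitution_models import (
    ExchangeabilityMatrix,
    FrequencyProfile,
    SubstitutionModel,
    build_rate_matrix,
    discrete_gamma_rates,
    get_exchangeability,
    smooth_profile,
    SpectralDecomposition,
)
from .benchmark import AdequacyResult, UndefinedZError, aa_diversity
from .likelihood_ml import observed_frequencies

N_EXCH = 190  # free entries of a symmetric 20x20 with zero diagonal

__all__ = [
    "DpConfig",
    "McmcState",
    "McmcTrace",
    "PosteriorSummary",
    "ConvergenceReport",
    "run_mcmc",
    "gibbs_allocate",
    "posterior_summary",
    "ppa_zscore",
    "convergence_diagnostics",
    "effective_sample_size",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class DpConfig:
    nmax: int = 1_000
    base_concentration: float = 1.0  # scales the base-measure concentration
    sample_base_concentration: bool = True  # hierarchical delta (MH-sampled)
    dp_alpha: float = 1.0
    dp_alpha_hyperprior: bool = True  # Gamma(1,1) hyperprior with MH update
    n_cycles: int = 10_000
    burnin: int = 5_000
    aux_m: int = 3
    allocation_sweeps: int = 1  # site-allocation Gibbs passes per cycle
    split_merge_moves: int = 3  # sequentially-allocated split-merge proposals per cycle
    gamma_ncat: int = 4
    n_branch_moves: int = 3
    snapshot_every: int = 5
    thin: int = 1
    fixed_exchangeabilities: str | None = None  # e.g. 'WAG' for a WAG-CAT analog

    def __post_init__(self):
        if self.nmax < 1:
            raise ValueError("nmax must be >= 1")
        if not 0 <= self.burnin < self.n_cycles:
            raise ValueError("burnin must be < n_cycles")

    @staticmethod
    def desk(n_cycles: int = 2_000, burnin: int = 1_000, **kw) -> "DpConfig":
        """Reduced-scale preset for interactive/desk use."""
        return DpConfig(n_cycles=n_cycles, burnin=burnin, **kw)

    @staticmethod
    def paper_scale(**kw) -> "DpConfig":
        return DpConfig(n_cycles=10_000, burnin=5_000, **kw)


@dataclass
class McmcState:
    z: np.ndarray  # site -> occupied-category index
    profiles: list[np.ndarray]  # one 20-simplex per occupied category
    exch: np.ndarray  # 190-simplex (upper-triangle order)
    bl: np.ndarray  # branch length per non-root postorder node
    alpha: float
    topology: str
    dp_alpha: float
    base_delta: float = 20.0  # base-measure total concentration (sampled)

    @property
    def n_categories(self) -> int:
        return len(self.profiles)

    def category_counts(self) -> np.ndarray:
        return np.bincount(self.z, minlength=self.n_categories)


@dataclass
class McmcTrace:
    lnl: np.ndarray
    nmode: np.ndarray
    alpha: np.ndarray
    tree_length: np.ndarray
    topology: list[str]
    tagged_lengths: dict[str, np.ndarray]
    thin: int = 1

    def __len__(self) -> int:
        return len(self.lnl)

    def to_tsv(self, path: str) -> None:
        tags = sorted(self.tagged_lengths)
        with open(path, "w") as fh:
            fh.write("cycle\tlnL\tNmode\talpha\ttreelength\ttopology")
            fh.write("".join(f"\t{t}" for t in tags) + "\n")
            for i in range(len(self)):
                row = (
                    f"{i * self.thin}\t{self.lnl[i]:.6f}\t{self.nmode[i]}"
                    f"\t{self.alpha[i]:.6f}\t{self.tree_length[i]:.6f}\t{self.topology[i]}"
                )
                row += "".join(f"\t{self.tagged_lengths[t][i]:.6f}" for t in tags)
                fh.write(row + "\n")


@dataclass
class PosteriorSummary:
    split_pp: dict[str, float]
    branch_length_mean: dict[str, float | None]
    branch_length_median: dict[str, float | None]
    nmode_mode: int
    nmode_mean: float
    nmode_range: tuple[int, int]


@dataclass
class ConvergenceReport:
    maxdiff: float
    effsize: float
    rel_diff: float


# ---------------------------------------------------------------------------
# Utilities


def _triu_to_matrix(r: np.ndarray) -> np.ndarray:
    m = np.zeros((20, 20))
    iu = np.triu_indices(20, k=1)
    m[iu] = r
    return m + m.T


def _matrix_to_triu(m: np.ndarray) -> np.ndarray:
    return m[np.triu_indices(20, k=1)]


def _dirichlet_logpdf(x: np.ndarray, conc: np.ndarray) -> float:
    x = np.maximum(x, 1e-300)
    return float(
        gammaln(conc.sum()) - gammaln(conc).sum() + ((conc - 1.0) * np.log(x)).sum()
    )


def effective_sample_size(x: np.ndarray) -> float:
    """n / (1 + 2 sum rho_k), autocorrelation truncated at the first
    non-positive lag."""
    x = np.asarray(x, float)
    n = x.size
    x = x - x.mean()
    var = float(x @ x) / n
    if var == 0 or n < 3:
        return float(n)
    s = 0.0
    for k in range(1, n):
        rho = float(x[:-k] @ x[k:]) / ((n - k) * var)
        if rho <= 0:
            break
        s += rho
    return n / (1.0 + 2.0 * s)


# ---------------------------------------------------------------------------
# Core sampler


class _Sampler:
    def __init__(
        self,
        aln: Alignment,
        trees: dict[str, Tree],
        start_topology: str,
        model_class: str,
        config: DpConfig,
        rng: np.random.Generator,
    ):
        self.aln = aln
        self.cfg = config
        self.rng = rng
        self.model_class = model_class.lower()
        if self.model_class not in ("gtr+g", "cat-gtr+g"):
            raise ValueError(f"unknown model class {model_class!r}")
        self.is_cat = self.model_class == "cat-gtr+g"

        self.trees = trees
        self.labels = list(trees)
        self.tarrs = {lab: TreeArrays.from_tree(t, aln.taxa) for lab, t in trees.items()}
        # edge identity across candidate topologies, by the leaf set below
        self.edge_sets: dict[str, list[frozenset[str]]] = {}
        for lab, tree in trees.items():
            below = tree.leafsets_below()
            order = [n for n in tree.postorder()][:-1]
            self.edge_sets[lab] = [frozenset(below[n]) for n in order]

        patterns, inverse, _counts = compress_patterns(aln)
        self.patterns = patterns
        self.pat_of_site = inverse
        self.n_sites = aln.n_sites

        if config.fixed_exchangeabilities:
            fixed = get_exchangeability(config.fixed_exchangeabilities).entries
            exch = _matrix_to_triu(fixed)
            exch = exch / exch.sum()
            self.exch_free = False
        else:
            exch = _matrix_to_triu(get_exchangeability("WAG").entries)
            exch = exch / exch.sum()
            self.exch_free = True

        profile0 = smooth_profile(observed_frequencies(aln))
        # Hierarchical base measure: Dirichlet(delta * observed frequencies)
        # with the total concentration delta sampled (log-uniform prior).  On
        # homogeneous data delta grows, prior-penalizing distinct profiles so
        # superfluous categories collapse; on heterogeneous data it stays small.
        self.base_center = profile0
        tarr = self.tarrs[start_topology]
        self.state = McmcState(
            z=np.zeros(self.n_sites, dtype=np.int64),
            profiles=[profile0],
            exch=exch,
            bl=np.clip(tarr.lengths[:-1].copy(), 1e-6, 50.0),
            alpha=0.6,
            topology=start_topology,
            dp_alpha=config.dp_alpha,
            base_delta=20.0 * config.base_concentration,
        )
        self._refresh_all_sll()

    @property
    def base_conc(self) -> np.ndarray:
        return self.state.base_delta * self.base_center

    # -- likelihood plumbing -------------------------------------------------

    def _rates(self, alpha: float):
        return discrete_gamma_rates(alpha, self.cfg.gamma_ncat)

    def _profile_sll(
        self,
        profile: np.ndarray,
        topology: str | None = None,
        bl: np.ndarray | None = None,
        alpha: float | None = None,
        exch: np.ndarray | None = None,
    ) -> np.ndarray:
        """Per-pattern log-likelihood under one category profile."""
        st = self.state
        topology = topology or st.topology
        bl = st.bl if bl is None else bl
        alpha = st.alpha if alpha is None else alpha
        exch = st.exch if exch is None else exch
        pi = smooth_profile(profile)
        R = ExchangeabilityMatrix("free", _triu_to_matrix(exch))
        Q = build_rate_matrix(R, FrequencyProfile(pi))
        sp = SpectralDecomposition(Q, pi)
        rates = self._rates(alpha)
        tarr = self.tarrs[topology].with_lengths(bl)
        return component_site_loglik(tarr, self.patterns, sp, rates.rates, rates.probs)

    def _sll_for(self, profiles, **kw) -> np.ndarray:
        return np.stack([self._profile_sll(p, **kw) for p in profiles])

    def _refresh_all_sll(self) -> None:
        self.sll = self._sll_for(self.state.profiles)

    def log_likelihood(self, sll: np.ndarray | None = None, z: np.ndarray | None = None) -> float:
        sll = self.sll if sll is None else sll
        z = self.state.z if z is None else z
        return float(sll[z, self.pat_of_site].sum())

    def _log_prior_bl(self, bl: np.ndarray) -> float:
        return float(bl.size * np.log(10.0) - 10.0 * bl.sum())

    # -- moves ---------------------------------------------------------------

    def allocation_sweep(self) -> None:
        """Gibbs over all sites (Neal's Algorithm 8 with a shared pool).

        Occupied categories are weighted by occupancy; each of m unoccupied
        auxiliary components (base-measure draws) carries mass dp_alpha / m.
        A category emptied during the sweep is dead — its adapted profile
        must not re-enter as a fresh table — and an auxiliary slot that gains
        a site becomes a real category and is replaced by a new draw, so m
        fresh slots are always on offer."""
        st, cfg, rng = self.state, self.cfg, self.rng
        m = cfg.aux_m

        profiles = list(st.profiles)
        sll_rows = [row for row in self.sll]
        cols = [row[self.pat_of_site] for row in sll_rows]
        counts = np.bincount(st.z, minlength=len(profiles)).astype(float).tolist()
        aux_slots: list[int] = []

        def add_aux() -> None:
            prof = smooth_profile(rng.dirichlet(self.base_conc))
            row = self._profile_sll(prof)
            profiles.append(prof)
            sll_rows.append(row)
            cols.append(row[self.pat_of_site])
            counts.append(0.0)
            aux_slots.append(len(profiles) - 1)

        for _ in range(m):
            add_aux()

        z = st.z
        order = rng.permutation(self.n_sites)
        u = rng.random(self.n_sites)
        for i in order:
            k_old = int(z[i])
            counts[k_old] -= 1.0
            cvec = np.array(counts)
            weights = np.where(cvec > 0, cvec, 0.0)
            n_occ = int((cvec > 0).sum())
            if n_occ < cfg.nmax:
                for a in aux_slots:
                    weights[a] = st.dp_alpha / m
            with np.errstate(divide="ignore"):
                logp = np.log(weights) + np.array([c[i] for c in cols])
            logp -= logp.max()
            cum = np.cumsum(np.exp(logp))
            k_new = int(np.searchsorted(cum, u[i] * cum[-1]))
            k_new = min(k_new, len(weights) - 1)
            z[i] = k_new
            counts[k_new] += 1.0
            if k_new in aux_slots:  # a fresh table opened: replenish the pool
                aux_slots.remove(k_new)
                add_aux()
        occupied = np.flatnonzero(
            np.bincount(z, minlength=len(profiles)) > 0
        )
        remap = {int(old): new for new, old in enumerate(occupied)}
        st.z = np.array([remap[int(k)] for k in z], dtype=np.int64)
        st.profiles = [profiles[int(k)] for k in occupied]
        self.sll = np.stack([sll_rows[int(k)] for k in occupied])

    def split_merge_move(self) -> None:
        """Sequentially-allocated split-merge (Dahl-style, non-conjugate).

        Two random distinct sites anchor the move: same category -> propose a
        split (new profile drawn from the base measure, remaining sites placed
        by restricted Gibbs), different categories -> propose the reverse
        merge.  The base-measure density of the new profile cancels between
        target and proposal, so acceptance needs only the likelihood change,
        the CRP occupancy factors and the sequential-allocation probability.
        Merges of near-duplicate categories are accepted readily, which is
        what lets the chain collapse to one profile on homogeneous data.
        """
        st, rng = self.state, self.rng
        if self.n_sites < 2:
            return
        i, j = rng.choice(self.n_sites, size=2, replace=False)
        zi, zj = int(st.z[i]), int(st.z[j])
        pats = self.pat_of_site
        if zi == zj:
            if st.n_categories >= min(self.cfg.nmax, self.n_sites):
                return
            members = np.flatnonzero(st.z == zi)
            others = members[(members != i) & (members != j)]
            phi_new = smooth_profile(rng.dirichlet(self.base_conc))
            row_new = self._profile_sll(phi_new)
            row_old = self.sll[zi]
            # restricted Gibbs: anchor i -> old category, j -> new category
            in_new = np.zeros(self.n_sites, dtype=bool)
            in_new[j] = True
            n_old, n_new = 1.0, 1.0
            logq = 0.0
            delta_ll = float(row_new[pats[j]] - row_old[pats[j]])
            for s in rng.permutation(others):
                lo = np.log(n_old) + row_old[pats[s]]
                ln = np.log(n_new) + row_new[pats[s]]
                mx = max(lo, ln)
                p_new = np.exp(ln - mx) / (np.exp(lo - mx) + np.exp(ln - mx))
                if rng.random() < p_new:
                    in_new[s] = True
                    n_new += 1.0
                    logq += np.log(p_new)
                    delta_ll += float(row_new[pats[s]] - row_old[pats[s]])
                else:
                    n_old += 1.0
                    logq += np.log1p(-p_new)
            n_tot = n_old + n_new
            accept = (
                delta_ll
                + np.log(st.dp_alpha)
                + gammaln(n_old)
                + gammaln(n_new)
                - gammaln(n_tot)
                - logq
            )
            if np.log(rng.random()) < accept:
                st.profiles.append(phi_new)
                st.z[in_new] = st.n_categories - 1
                self.sll = np.vstack([self.sll, row_new[None, :]])
        else:
            members_i = np.flatnonzero(st.z == zi)
            members_j = np.flatnonzero(st.z == zj)
            others = np.concatenate([members_i, members_j])
            others = others[(others != i) & (others != j)]
            row_i, row_j = self.sll[zi], self.sll[zj]
            # probability that the reverse split reproduces the current state
            n_old, n_new = 1.0, 1.0
            logq = 0.0
            for s in rng.permutation(others):
                lo = np.log(n_old) + row_i[pats[s]]
                ln = np.log(n_new) + row_j[pats[s]]
                mx = max(lo, ln)
                p_new = np.exp(ln - mx) / (np.exp(lo - mx) + np.exp(ln - mx))
                if st.z[s] == zj:
                    logq += np.log(max(p_new, 1e-300))
                    n_new += 1.0
                else:
                    logq += np.log(max(1.0 - p_new, 1e-300))
                    n_old += 1.0
            delta_ll = float(
                (row_i[pats[members_j]] - row_j[pats[members_j]]).sum()
            )
            accept = (
                delta_ll
                - np.log(st.dp_alpha)
                - gammaln(n_old)
                - gammaln(n_new)
                + gammaln(n_old + n_new)
                + logq
            )
            if np.log(rng.random()) < accept:
                st.z[members_j] = zi
                st.profiles.pop(zj)
                st.z = np.where(st.z > zj, st.z - 1, st.z)
                self.sll = np.delete(self.sll, zj, axis=0)

    def update_profiles(self) -> None:
        st, rng = self.state, self.rng
        for k in range(st.n_categories):
            sites = np.flatnonzero(st.z == k)
            cnt = np.bincount(self.pat_of_site[sites], minlength=self.patterns.shape[1])
            cur = st.profiles[k]
            scale = float(rng.choice([100.0, 1000.0]))
            prop_conc = scale * cur + 0.5
            prop = smooth_profile(rng.dirichlet(prop_conc))
            back_conc = scale * prop + 0.5
            new_row = self._profile_sll(prop)
            delta_ll = float(cnt @ (new_row - self.sll[k]))
            delta_prior = float(
                (self.base_conc - 1.0)
                @ (
                    np.log(np.maximum(prop, 1e-300))
                    - np.log(np.maximum(cur, 1e-300))
                )
            )
            hastings = _dirichlet_logpdf(cur, back_conc) - _dirichlet_logpdf(
                prop, prop_conc
            )
            if np.log(rng.random()) < delta_ll + delta_prior + hastings:
                st.profiles[k] = prop
                self.sll[k] = new_row

    def _try_global(self, **proposal) -> bool:
        """Generic MH step for moves that invalidate every category row."""
        st = self.state
        extra = proposal.pop("extra_log_ratio", 0.0)
        new_sll = self._sll_for(st.profiles, **proposal)
        delta = self.log_likelihood(new_sll) - self.log_likelihood() + extra
        if np.log(self.rng.random()) < delta:
            self.sll = new_sll
            return True
        return False

    def update_gtr(self) -> None:
        if not self.exch_free:
            return
        st, rng = self.state, self.rng
        scale = float(rng.choice([3000.0, 30000.0]))
        cur = st.exch
        prop_conc = scale * cur + 0.5
        prop = rng.dirichlet(prop_conc)
        prop = np.maximum(prop, 1e-12)
        prop /= prop.sum()
        back_conc = scale * prop + 0.5
        hastings = _dirichlet_logpdf(cur, back_conc) - _dirichlet_logpdf(prop, prop_conc)
        if self._try_global(exch=prop, extra_log_ratio=hastings):
            st.exch = prop

    def update_branch_lengths(self) -> None:
        st, rng = self.state, self.rng
        # tree-length scaling
        factor = float(np.exp(0.4 * (rng.random() - 0.5)))
        prop = st.bl * factor
        ratio = (
            self._log_prior_bl(prop)
            - self._log_prior_bl(st.bl)
            + st.bl.size * np.log(factor)
        )
        if self._try_global(bl=prop, extra_log_ratio=ratio):
            st.bl = prop
        # single-branch multiplicative moves
        for _ in range(self.cfg.n_branch_moves):
            e = int(rng.integers(st.bl.size))
            factor = float(np.exp(1.0 * (rng.random() - 0.5)))
            prop = st.bl.copy()
            prop[e] = min(st.bl[e] * factor, 100.0)
            ratio = (
                self._log_prior_bl(prop) - self._log_prior_bl(st.bl) + np.log(factor)
            )
            if self._try_global(bl=prop, extra_log_ratio=ratio):
                st.bl = prop

    def update_alpha(self) -> None:
        st, rng = self.state, self.rng
        if rng.random() < 0.2:  # independence draw from the log-uniform prior
            prop = float(np.exp(rng.uniform(np.log(0.05), np.log(50.0))))
        else:  # multiplicative walk; prior and proposal terms cancel exactly
            prop = float(st.alpha * np.exp(0.5 * (rng.random() - 0.5)))
            if not (0.05 <= prop <= 50.0):
                return
        if self._try_global(alpha=prop):
            st.alpha = prop

    def update_base_delta(self) -> None:
        """MH on the base-measure concentration given the current profiles.

        Exponential(mean 50) prior: large enough to tighten on homogeneous
        data, but it keeps the base measure proper so the profile mixture
        never degenerates into an unidentified-partition regime."""
        if not self.cfg.sample_base_concentration:
            return
        st, rng = self.state, self.rng
        step = float(rng.choice([0.8, 3.0]))  # small/large mixture for traversal
        prop = float(st.base_delta * np.exp(step * (rng.random() - 0.5)))
        if not (1.0 <= prop <= 1e6):
            return
        cur_conc = st.base_delta * self.base_center
        prop_conc = prop * self.base_center
        delta = sum(
            _dirichlet_logpdf(p, prop_conc) - _dirichlet_logpdf(p, cur_conc)
            for p in st.profiles
        )
        delta += -(prop - st.base_delta) / 10.0  # Exponential(mean 10) prior
        delta += np.log(prop) - np.log(st.base_delta)  # multiplicative Hastings
        if np.log(rng.random()) < delta:
            st.base_delta = prop

    def update_dp_alpha(self) -> None:
        st, rng = self.state, self.rng
        if not (self.is_cat and self.cfg.dp_alpha_hyperprior):
            return
        cur, K, n = st.dp_alpha, st.n_categories, self.n_sites

        def crp_term(a: float) -> float:
            return K * np.log(a) + gammaln(a) - gammaln(a + n)

        def log_prior(a: float) -> float:
            # Gamma(shape 0.2, scale 0.5): mass near zero, so when the data do
            # not demand extra categories the concentration settles small and
            # the occupied-category count collapses; heterogeneous data still
            # sustain many categories because their prior cost is dwarfed by
            # the likelihood gain of distinct site profiles
            return -0.8 * np.log(a) - 2.0 * a

        prop = float(cur * np.exp(0.7 * (rng.random() - 0.5)))
        delta = (
            crp_term(prop)
            - crp_term(cur)
            + log_prior(prop)
            - log_prior(cur)
            + np.log(prop)
            - np.log(cur)
        )
        if np.log(rng.random()) < delta:
            st.dp_alpha = prop

    def topology_move(self) -> None:
        st, rng = self.state, self.rng
        if len(self.labels) < 2:
            return
        others = [lab for lab in self.labels if lab != st.topology]
        prop_label = others[int(rng.integers(len(others)))]
        new_internal = float(rng.exponential(0.1))
        new_bl = self._map_lengths(st.topology, st.bl, prop_label, new_internal)
        # internal branch drawn from its prior: prior and proposal cancel
        new_sll = self._sll_for(st.profiles, topology=prop_label, bl=new_bl)
        delta = self.log_likelihood(new_sll) - self.log_likelihood()
        if np.log(rng.random()) < delta:
            st.topology, st.bl = prop_label, new_bl
            self.sll = new_sll

    def _map_lengths(
        self, from_label: str, bl: np.ndarray, to_label: str, new_internal: float
    ) -> np.ndarray:
        src = {s: bl[i] for i, s in enumerate(self.edge_sets[from_label])}
        out = np.empty(len(self.edge_sets[to_label]))
        for i, s in enumerate(self.edge_sets[to_label]):
            out[i] = src.get(s, new_internal)
        return out

    # -- cycle ---------------------------------------------------------------

    def sweep(self) -> None:
        if self.is_cat:
            for _ in range(self.cfg.allocation_sweeps):
                self.allocation_sweep()
            for _ in range(self.cfg.split_merge_moves):
                self.split_merge_move()
        self.update_profiles()
        self.update_base_delta()
        self.update_gtr()
        self.update_branch_lengths()
        self.update_alpha()
        self.update_dp_alpha()
        self.topology_move()

    def tree_with_current_lengths(self, label: str | None = None, bl=None) -> Tree:
        label = label or self.state.topology
        bl = self.state.bl if bl is None else bl
        tree = self.trees[label].copy()
        for node, length in zip(tree.postorder(), bl):
            node.length = float(length)
        return tree

    def snapshot(self) -> dict:
        st = self.state
        return {
            "z": st.z.copy(),
            "profiles": [p.copy() for p in st.profiles],
            "exch": st.exch.copy(),
            "bl": st.bl.copy(),
            "alpha": st.alpha,
            "topology": st.topology,
            "dp_alpha": st.dp_alpha,
            "base_delta": st.base_delta,
        }


def gibbs_allocate(
    sampler_or_state,
    site: int,
    m: int,
    rng: np.random.Generator,
    loglik_rows: np.ndarray | None = None,
    dp_alpha: float | None = None,
) -> None:
    """Single-site allocation Gibbs update (exposed mainly for prior-only
    validation).  With ``loglik_rows=None`` the likelihood is flat and the
    update is exactly the Chinese-restaurant conditional."""
    st: McmcState = sampler_or_state
    counts = st.category_counts().astype(float)
    k_old = int(st.z[site])
    counts[k_old] -= 1.0
    a = st.dp_alpha if dp_alpha is None else dp_alpha
    weights = np.concatenate([counts, np.full(m, a / m)])
    ll = np.zeros(weights.size) if loglik_rows is None else loglik_rows
    with np.errstate(divide="ignore"):
        logp = np.log(weights) + ll
    logp -= logsumexp(logp)
    k_new = int(rng.choice(weights.size, p=np.exp(logp)))
    n_occ = len(st.profiles)
    if k_new >= n_occ:  # seat at a fresh table
        st.profiles.append(smooth_profile(rng.dirichlet(np.ones(20))))
        k_new = len(st.profiles) - 1
    st.z[site] = k_new
    # drop the old category if the move emptied it
    if k_old != k_new and (st.z == k_old).sum() == 0:
        st.profiles.pop(k_old)
        st.z = np.where(st.z > k_old, st.z - 1, st.z)


# ---------------------------------------------------------------------------
# Public driver


def run_mcmc(
    aln: Alignment,
    tree: Tree,
    model_class: str,
    config: DpConfig,
    rng: np.random.Generator,
    candidates: dict[str, Tree] | None = None,
    tags: tuple[str, ...] = ("AB", "EF", "ABEF", "ABCD", "ABGHIJ"),
    checkpoint_path: str | None = None,
    resume_from: str | dict | None = None,
) -> tuple[McmcTrace, list[dict]]:
    """One chain.  With ``candidates`` the focal topology is sampled; otherwise
    the topology is fixed at the input tree.  Returns the trace and the list of
    post-hoc state snapshots (every ``config.snapshot_every`` cycles)."""
    trees = candidates or {"fixed": tree}
    start = next(iter(trees)) if candidates is None else _matching_label(tree, trees)
    sampler = _Sampler(aln, trees, start, model_class, config, rng)

    start_cycle = 0
    records: list[dict] = []
    snapshots: list[dict] = []
    if resume_from is not None:
        payload = (
            json.load(open(resume_from)) if isinstance(resume_from, str) else resume_from
        )
        _restore(sampler, payload, rng)
        start_cycle = payload["cycle"]
        records = payload["records"]
        snapshots = [_snapshot_from_json(s) for s in payload["snapshots"]]

    tag_list = [t for t in tags]
    for cycle in range(start_cycle, config.n_cycles):
        sampler.sweep()
        st = sampler.state
        if cycle % config.thin == 0:
            cur_tree = sampler.tree_with_current_lengths()
            records.append(
                {
                    "lnl": sampler.log_likelihood(),
                    "nmode": st.n_categories,
                    "alpha": st.alpha,
                    "tree_length": float(st.bl.sum()),
                    "topology": st.topology,
                    "tagged": {
                        t: clade_branch_length(cur_tree, t)
                        for t in tag_list
                        if t in cur_tree.clades
                    },
                }
            )
        if cycle % config.snapshot_every == 0:
            snap = sampler.snapshot()
            snap["cycle"] = cycle
            snapshots.append(snap)
        if checkpoint_path and (cycle + 1) % max(1, config.n_cycles // 4) == 0:
            save_checkpoint(checkpoint_path, sampler, cycle + 1, records, snapshots, rng)

    trace = _records_to_trace(records, tag_list, config.thin)
    return trace, snapshots


def _matching_label(tree: Tree, trees: dict[str, Tree]) -> str:
    from .trees_io import bipartitions

    target = bipartitions(tree)
    for lab, t in trees.items():
        if bipartitions(t) == target:
            return lab
    return next(iter(trees))


def _records_to_trace(records: list[dict], tags: list[str], thin: int) -> McmcTrace:
    n = len(records)
    tagged = {
        t: np.array(
            [r["tagged"].get(t, np.nan) if r["tagged"].get(t) is not None else np.nan for r in records]
        )
        for t in tags
    }
    return McmcTrace(
        lnl=np.array([r["lnl"] for r in records]),
        nmode=np.array([r["nmode"] for r in records], dtype=int),
        alpha=np.array([r["alpha"] for r in records]),
        tree_length=np.array([r["tree_length"] for r in records]),
        topology=[r["topology"] for r in records],
        tagged_lengths=tagged,
        thin=thin,
    )


# ---------------------------------------------------------------------------
# Checkpointing (versioned text serialization)


def save_checkpoint(path, sampler: _Sampler, cycle, records, snapshots, rng) -> None:
    payload = {
        "version": 1,
        "cycle": cycle,
        "state": _snapshot_to_json(sampler.snapshot()),
        "records": records,
        "snapshots": [_snapshot_to_json(s) for s in snapshots],
        "rng_state": rng.bit_generator.state,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _snapshot_to_json(s: dict) -> dict:
    out = dict(s)
    out["z"] = s["z"].tolist()
    out["profiles"] = [p.tolist() for p in s["profiles"]]
    out["exch"] = s["exch"].tolist()
    out["bl"] = s["bl"].tolist()
    return out


def _snapshot_from_json(s: dict) -> dict:
    out = dict(s)
    out["z"] = np.array(s["z"], dtype=np.int64)
    out["profiles"] = [np.array(p) for p in s["profiles"]]
    out["exch"] = np.array(s["exch"])
    out["bl"] = np.array(s["bl"])
    return out


def _restore(sampler: _Sampler, payload: dict, rng: np.random.Generator) -> None:
    snap = _snapshot_from_json(payload["state"])
    st = sampler.state
    st.z = snap["z"]
    st.profiles = snap["profiles"]
    st.exch = snap["exch"]
    st.bl = snap["bl"]
    st.alpha = snap["alpha"]
    st.topology = snap["topology"]
    st.dp_alpha = snap["dp_alpha"]
    st.base_delta = snap.get("base_delta", 20.0)
    rng.bit_generator.state = payload["rng_state"]
    sampler._refresh_all_sll()


# ---------------------------------------------------------------------------
# Summaries, adequacy, convergence


def posterior_summary(trace: McmcTrace, burnin: int) -> PosteriorSummary:
    if burnin >= len(trace):
        raise ValueError("burnin leaves no post-burnin samples")
    sl = slice(burnin, None)
    topo = trace.topology[sl.start :]
    labels = sorted(set(trace.topology))
    n = len(topo)
    pp = {lab: topo.count(lab) / n for lab in labels}
    bl_mean: dict[str, float | None] = {}
    bl_median: dict[str, float | None] = {}
    for tag, vals in trace.tagged_lengths.items():
        v = vals[sl]
        good = v[~np.isnan(v)]
        bl_mean[tag] = float(good.mean()) if good.size else None
        bl_median[tag] = float(np.median(good)) if good.size else None
    nm = trace.nmode[sl]
    values, counts = np.unique(nm, return_counts=True)
    mode = int(values[np.flatnonzero(counts == counts.max())[0]])  # tie -> smaller
    return PosteriorSummary(
        split_pp=pp,
        branch_length_mean=bl_mean,
        branch_length_median=bl_median,
        nmode_mode=mode,
        nmode_mean=float(nm.mean()),
        nmode_range=(int(nm.min()), int(nm.max())),
    )


def ppa_zscore(
    snapshots: list[dict],
    trees: dict[str, Tree],
    observed: Alignment,
    n_draws: int,
    rng: np.random.Generator,
    burnin: int = 0,
    gamma_ncat: int = 4,
) -> AdequacyResult:
    """Posterior-predictive diversity Z: replicate alignments simulated from
    ``n_draws`` equally spaced post-burnin states."""
    usable = [s for s in snapshots if s.get("cycle", 0) >= burnin]
    if not usable:
        raise ValueError("no post-burnin snapshots available")
    idx = np.linspace(0, len(usable) - 1, min(n_draws, len(usable))).astype(int)
    d_obs = aa_diversity(observed)
    reps = np.empty(idx.size)
    taxa = observed.taxa
    for j, i in enumerate(idx):
        snap = usable[int(i)]
        reps[j] = aa_diversity(_simulate_from_snapshot(snap, trees, taxa, observed.n_sites, rng, gamma_ncat))
    sd = float(reps.std(ddof=1))
    if sd == 0.0:
        raise UndefinedZError("posterior-predictive diversity has zero spread", reps)
    # positive Z = model over-predicts diversity (fails on sharp site profiles)
    return AdequacyResult(
        z_score=float((reps.mean() - d_obs) / sd),
        observed=d_obs,
        replicates=reps,
        mode="ppa",
    )


def _simulate_from_snapshot(
    snap: dict,
    trees: dict[str, Tree],
    taxa: list[str],
    n_sites: int,
    rng: np.random.Generator,
    gamma_ncat: int,
) -> Alignment:
    from .simulate import _sample_descendants

    tree = trees[snap["topology"]].copy()
    for node, length in zip(tree.postorder(), snap["bl"]):
        node.length = float(length)
    R = ExchangeabilityMatrix("free", _triu_to_matrix(np.asarray(snap["exch"])))
    rates = discrete_gamma_rates(snap["alpha"], gamma_ncat)
    z = np.asarray(snap["z"])
    rate_idx = rng.integers(0, gamma_ncat, size=n_sites)
    row = {name: i for i, name in enumerate(tree.leaf_names)}
    codes = np.empty((len(row), n_sites), dtype=np.uint8)
    nodes = list(tree.preorder())
    for k in np.unique(z):
        pi = smooth_profile(np.asarray(snap["profiles"][int(k)]))
        Q = build_rate_matrix(ExchangeabilityMatrix("free", R.entries), FrequencyProfile(pi))
        sp = SpectralDecomposition(Q, pi)
        for g in range(gamma_ncat):
            idx = np.flatnonzero((z == k) & (rate_idx == g))
            if idx.size == 0:
                continue
            states = {id(nodes[0]): rng.choice(20, size=idx.size, p=sp.pi).astype(np.uint8)}
            for node in nodes:
                if node.parent is None:
                    continue
                P = sp.transition(node.length * rates.rates[g])
                states[id(node)] = _sample_descendants(states[id(node.parent)], P, rng)
            for node in nodes:
                if node.is_leaf:
                    codes[row[node.name], idx] = states[id(node)]
    order = [tree.leaf_names.index(t) for t in taxa]
    return Alignment(taxa, codes[order])


def convergence_diagnostics(
    trace_a: McmcTrace, trace_b: McmcTrace, burnin: int
) -> ConvergenceReport:
    if len(trace_a) != len(trace_b):
        raise ValueError("traces must have equal length")
    sa = posterior_summary(trace_a, burnin)
    sb = posterior_summary(trace_b, burnin)
    labels = set(sa.split_pp) | set(sb.split_pp)
    maxdiff = max(
        abs(sa.split_pp.get(lab, 0.0) - sb.split_pp.get(lab, 0.0)) for lab in labels
    )
    scalars_a = [trace_a.lnl, trace_a.alpha, trace_a.tree_length, trace_a.nmode.astype(float)]
    scalars_b = [trace_b.lnl, trace_b.alpha, trace_b.tree_length, trace_b.nmode.astype(float)]
    eff = min(
        min(effective_sample_size(x[burnin:]) for x in scalars_a),
        min(effective_sample_size(x[burnin:]) for x in scalars_b),
    )
    rel = 0.0
    for xa, xb in zip(scalars_a, scalars_b):
        a, b = xa[burnin:], xb[burnin:]
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
        if pooled == 0:
            continue
        rel = max(rel, abs(a.mean() - b.mean()) / pooled)
    return ConvergenceReport(maxdiff=float(maxdiff), effsize=float(eff), rel_diff=float(rel))
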