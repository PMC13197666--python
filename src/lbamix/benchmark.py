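"""Study orchestration and metrics: the shared amino-acid diversity statistic,
replicate classification, recovery/performance tables, branch-length reports
and the end-to-end experiment runner."""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .trees_io import Alignment, Tree, clade_branch_length

__all__ = [
    "AdequacyResult",
    "UndefinedZError",
    "ReplicateOutcome",
    "aa_diversity",
    "classify_replicate",
    "recovery_table",
    "branch_length_report",
    "run_experiment",
    "ExperimentConfig",
]


class UndefinedZError(RuntimeError):
    def __init__(self, message: str, replicates: np.ndarray):
        super().__init__(message)
        self.replicates = replicates


@dataclass
class AdequacyResult:
    """Diversity Z-score: fit declared when -2 < Z < 2."""

    z_score: float
    observed: float
    replicates: np.ndarray
    mode: str  # 'pb' (ML parametric bootstrap) or 'ppa' (posterior predictive)

    @property
    def fits(self) -> bool:
        return -2.0 < self.z_score < 2.0


def aa_diversity(aln: Alignment) -> float:
    """Mean over columns of the number of distinct amino acids observed.

    Gap/ambiguity codes are excluded from the distinct count; all-gap columns
    are dropped from the mean entirely."""
    codes = aln.codes
    if codes.size == 0:
        raise ValueError("empty alignment")
    present = np.zeros((20, codes.shape[1]), dtype=bool)
    for a in range(20):
        present[a] = (codes == a).any(axis=0)
    distinct = present.sum(axis=0)
    usable = distinct > 0
    if not usable.any():
        raise ValueError("no usable (non-gap) columns")
    return float(distinct[usable].mean())


def classify_replicate(best_label: str, support: float | None, target_label: str) -> str:
    """'Correct' if the target split wins with support > 50, 'Wrong' if another
    split wins with support > 50, else 'Unresolved' (support <= 50 or absent)."""
    if support is None or support <= 50.0:
        return "Unresolved"
    return "Correct" if best_label == target_label else "Wrong"


@dataclass
class ReplicateOutcome:
    condition: str
    replicate: int
    model: str
    call: str  # Correct | Unresolved | Wrong
    support: float | None
    best_label: str | None = None
    branch_lengths: dict[str, float | None] = field(default_factory=dict)
    adequacy_z: float | None = None
    nmode_mode: int | None = None
    failed: bool = False


def recovery_table(outcomes: list[ReplicateOutcome]) -> pd.DataFrame:
    """Per (condition, model): RR/U/W percentages and Performance P = RR - W.

    Percentages are over all non-failed replicates, so RR + U + W = 100."""
    rows = []
    df = pd.DataFrame([asdict(o) for o in outcomes])
    if df.empty:
        return pd.DataFrame(columns=["condition", "model", "n", "RR", "U", "W", "P"])
    df = df[~df["failed"]]
    for (cond, model), grp in df.groupby(["condition", "model"], sort=False):
        n = len(grp)
        if n == 0:
            continue
        rr = 100.0 * (grp["call"] == "Correct").sum() / n
        u = 100.0 * (grp["call"] == "Unresolved").sum() / n
        w = 100.0 * (grp["call"] == "Wrong").sum() / n
        rows.append(
            {"condition": cond, "model": model, "n": n, "RR": rr, "U": u, "W": w, "P": rr - w}
        )
    return pd.DataFrame(rows)


def branch_length_report(
    outcomes: list[ReplicateOutcome], targets: dict[str, float]
) -> pd.DataFrame:
    """Per (condition, model, tag): quartile summary of inferred lengths and a
    flag for whether the target value falls inside the inferred range.

    Replicates whose inferred tree lacks the tagged clade contribute nothing
    for that tag (counted in ``n_missing``)."""
    rows = []
    by_group: dict[tuple[str, str], list[ReplicateOutcome]] = {}
    for o in outcomes:
        if not o.failed:
            by_group.setdefault((o.condition, o.model), []).append(o)
    for (cond, model), group in by_group.items():
        for tag, target in targets.items():
            vals = np.array(
                [
                    o.branch_lengths[tag]
                    for o in group
                    if o.branch_lengths.get(tag) is not None
                ]
            )
            n_missing = sum(1 for o in group if o.branch_lengths.get(tag) is None)
            if vals.size == 0:
                rows.append(
                    {
                        "condition": cond,
                        "model": model,
                        "tag": tag,
                        "n": 0,
                        "n_missing": n_missing,
                        "reason": "no replicate recovered this clade",
                    }
                )
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            lo, hi = float(vals.min()), float(vals.max())
            direction = ""
            if not (lo <= target <= hi):
                direction = "underestimate" if hi < target else "overestimate"
            rows.append(
                {
                    "condition": cond,
                    "model": model,
                    "tag": tag,
                    "n": int(vals.size),
                    "n_missing": n_missing,
                    "median": float(med),
                    "q1": float(q1),
                    "q3": float(q3),
                    "min": lo,
                    "max": hi,
                    "target": target,
                    "target_in_range": bool(lo <= target <= hi),
                    "direction": direction,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end experiment runner


@dataclass
class ExperimentConfig:
    """One benchmark condition: a simulated data class analyzed by a model panel."""

    name: str
    tree_fixture: str  # 'farris' | 'felsenstein'
    blmf: float
    data_class: str  # 'homogeneous' | 'heterogeneous'
    n_sites: int
    n_replicates: int
    base_seed: int
    models: tuple[str, ...] = ("MLHo", "GTR", "WAG-C10", "MLHe", "CAT-GTR")
    sharpness: float = 0.1  # synthetic-profile sharpness for heterogeneous data
    n_profiles: int = 100
    n_bootstrap: int = 100
    mcmc_cycles: int = 400
    mcmc_burnin: int = 200
    cxx_levels: tuple[str, ...] = ("C10", "C20", "C30", "C40", "C50", "C60")


def _target_label(fixture: str) -> str:
    from .trees_io import fixture_clade_config

    return fixture_clade_config()["resolutions"][fixture]


def _tagged_lengths(tree: Tree, tags: list[str]) -> dict[str, float | None]:
    return {tag: clade_branch_length(tree, tag) for tag in tags}


def _mixture_split_two_stage(
    aln: Alignment,
    candidates: dict[str, Tree],
    level: str,
    n_bootstrap: int,
    rng: np.random.Generator,
):
    """Per candidate: optimize branch lengths under homogeneous WAG+F+G, then
    EM the CXX component weights with those lengths fixed; RELL support."""
    from . import likelihood_ml as ML
    from .substitution_models import SubstitutionModel

    site_lls, lnls, trees = {}, {}, {}
    for label, cand in candidates.items():
        stage1 = ML.fit_model(
            aln, cand, SubstitutionModel.homogeneous("WAG"),
            ML.FitOptions(estimate_frequencies=True),
        )
        stage2 = ML.fit_model(
            aln,
            stage1.tree,
            ML._wag_cxx_model(level, 0.6, 4),
            ML.FitOptions(
                estimate_frequencies=True,
                estimate_weights=True,
                optimize_branch_lengths=False,
                optimize_alpha=False,
                max_outer=3,
            ),
        )
        site_lls[label] = stage2.site_log_likelihoods
        lnls[label] = stage2.log_likelihood
        trees[label] = stage2.tree
    best = max(lnls, key=lnls.get)
    support = None
    if n_bootstrap > 0:
        support = ML.rell_support(site_lls, best, n_bootstrap, rng)
    return best, support, trees[best]


def _analyze_replicate(
    cfg: ExperimentConfig,
    rep: int,
    aln: Alignment,
    candidates: dict[str, Tree],
    target: str,
    rng: np.random.Generator,
) -> list[ReplicateOutcome]:
    """Run the configured model panel on one replicate."""
    from . import bayes_cat, likelihood_ml
    from .substitution_models import SubstitutionModel

    report_tags = ["AB", "EF", "ABEF"]
    labels = sorted(candidates)
    selection_tree = candidates[labels[0]]  # data-independent choice
    outcomes = []
    for model_name in cfg.models:
        try:
            if model_name == "MLHo":
                best, _ = likelihood_ml.bic_select(
                    aln, selection_tree, likelihood_ml.mlho_candidates()
                )
                spec = best.model
                opts = likelihood_ml.FitOptions(
                    estimate_frequencies=best.frequencies is not None
                )
                call = likelihood_ml.evaluate_focal_split(
                    aln, candidates, spec, opts, n_bootstrap=cfg.n_bootstrap, rng=rng
                )
                best_fit = call.fits[call.best_label]
                outcomes.append(
                    ReplicateOutcome(
                        condition=cfg.name,
                        replicate=rep,
                        model=model_name,
                        call=classify_replicate(call.best_label, call.support, target),
                        support=call.support,
                        best_label=call.best_label,
                        branch_lengths=_tagged_lengths(best_fit.tree, report_tags),
                    )
                )
            elif model_name in ("WAG-C10", "MLHe", "C60"):
                if model_name == "WAG-C10":
                    level = "C10"
                elif model_name == "C60":
                    level = "C60"
                else:  # MLHe protocol: fixed C60 on homogeneous data, else BIC
                    if cfg.data_class == "homogeneous":
                        level = "C60"
                    else:
                        stage1 = likelihood_ml.fit_model(
                            aln,
                            selection_tree,
                            SubstitutionModel.homogeneous("WAG"),
                            likelihood_ml.FitOptions(estimate_frequencies=True),
                        )
                        fit, _protocol = likelihood_ml.select_mlhe(
                            aln,
                            stage1.tree,
                            is_homogeneous_protocol=False,
                            cxx_levels=cfg.cxx_levels,
                            options=likelihood_ml.FitOptions(
                                estimate_frequencies=True,
                                estimate_weights=True,
                                optimize_branch_lengths=False,
                                optimize_alpha=False,
                                max_outer=3,
                            ),
                        )
                        name = fit.name
                        level = name.split("+")[-1] if "C" in name.split("+")[-1] else "C10"
                best_label, support, best_tree = _mixture_split_two_stage(
                    aln, candidates, level, cfg.n_bootstrap, rng
                )
                outcomes.append(
                    ReplicateOutcome(
                        condition=cfg.name,
                        replicate=rep,
                        model=model_name,
                        call=classify_replicate(best_label, support, target),
                        support=support,
                        best_label=best_label,
                        branch_lengths=_tagged_lengths(best_tree, report_tags),
                    )
                )
            elif model_name in ("GTR", "CAT-GTR"):
                mc = bayes_cat.DpConfig(
                    n_cycles=cfg.mcmc_cycles, burnin=cfg.mcmc_burnin
                )
                start = candidates[labels[int(rng.integers(len(labels)))]]
                trace, _states = bayes_cat.run_mcmc(
                    aln,
                    start,
                    "gtr+g" if model_name == "GTR" else "cat-gtr+g",
                    mc,
                    rng,
                    candidates=candidates,
                )
                summ = bayes_cat.posterior_summary(trace, mc.burnin)
                best_label = max(summ.split_pp, key=summ.split_pp.get)
                support = 100.0 * summ.split_pp[best_label]
                outcomes.append(
                    ReplicateOutcome(
                        condition=cfg.name,
                        replicate=rep,
                        model=model_name,
                        call=classify_replicate(best_label, support, target),
                        support=support,
                        best_label=best_label,
                        branch_lengths={
                            t: summ.branch_length_mean.get(t) for t in report_tags
                        },
                        nmode_mode=summ.nmode_mode,
                    )
                )
            else:
                raise ValueError(f"unknown model panel entry {model_name!r}")
        except Exception:
            outcomes.append(
                ReplicateOutcome(
                    condition=cfg.name,
                    replicate=rep,
                    model=model_name,
                    call="Unresolved",
                    support=None,
                    failed=True,
                )
            )
    return outcomes


def run_experiment(
    configs: list[ExperimentConfig], out_dir: str, resume: bool = True
) -> tuple[pd.DataFrame, list[ReplicateOutcome]]:
    """Simulate-and-analyze loop over all conditions; resumable through an
    outcome JSONL ledger keyed by (condition, replicate, model)."""
    from .trees_io import apply_blmf, BlmfSpec, fixture_clade_config, load_fixture_tree
    from .trees_io import focal_split_resolutions
    from .substitution_models import (
        FrequencyProfile,
        SubstitutionModel,
        discrete_gamma_rates,
        get_default_frequencies,
        get_exchangeability,
        sample_profile_mixture,
    )
    from .simulate import simulate_alignment

    os.makedirs(out_dir, exist_ok=True)
    ledger_path = os.path.join(out_dir, "outcomes.jsonl")
    done: dict[tuple[str, int, str], ReplicateOutcome] = {}
    if resume and os.path.exists(ledger_path):
        with open(ledger_path) as fh:
            for line in fh:
                rec = json.loads(line)
                done[(rec["condition"], rec["replicate"], rec["model"])] = (
                    ReplicateOutcome(**rec)
                )

    outcomes: list[ReplicateOutcome] = list(done.values())
    quartet = fixture_clade_config()["quartet"]
    with open(ledger_path, "a") as ledger:
        for cfg in configs:
            base = load_fixture_tree(cfg.tree_fixture)
            tree = apply_blmf(base, BlmfSpec(cfg.blmf))
            candidates = focal_split_resolutions(tree, quartet)
            target = _target_label(cfg.tree_fixture)
            exch = get_exchangeability("WAG")
            rates = discrete_gamma_rates(0.6, 4)
            if cfg.data_class == "heterogeneous":
                mix_rng = np.random.default_rng(cfg.base_seed + 987654)
                mixture = sample_profile_mixture(
                    cfg.n_profiles,
                    FrequencyProfile(get_default_frequencies("WAG")),
                    cfg.sharpness,
                    1.0,
                    mix_rng,
                )
            else:
                mixture = SubstitutionModel.homogeneous("WAG").mixture
            model = SubstitutionModel(exch, mixture, rates, name=f"WAG-{cfg.data_class}")
            for rep in range(cfg.n_replicates):
                todo = [m for m in cfg.models if (cfg.name, rep, m) not in done]
                if not todo:
                    continue
                seed = cfg.base_seed + rep
                sim_rng = np.random.default_rng(seed)
                aln = simulate_alignment(tree, model, cfg.n_sites, sim_rng)
                sub_cfg = cfg
                if tuple(todo) != tuple(cfg.models):
                    from dataclasses import replace as dc_replace

                    sub_cfg = dc_replace(cfg, models=tuple(todo))
                new = _analyze_replicate(
                    sub_cfg, rep, aln, candidates, target, np.random.default_rng(seed + 10_000)
                )
                for o in new:
                    rec = asdict(o)
                    ledger.write(json.dumps(rec) + "\n")
                    ledger.flush()
                outcomes.extend(new)
    table = recovery_table(outcomes)
    table.to_csv(os.path.join(out_dir, "recovery.tsv"), sep="\t", index=False)
    return table, outcomes
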