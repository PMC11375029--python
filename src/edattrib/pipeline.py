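"""Study orchestration: candidate model grids, selection, and artifacts.

Per admission category the protocol fits a grid of candidate models
(family x maximum lag x with/without immediate-week effects), selects the
winner — by AIC among the likelihood-based families (Poisson, negative
binomial); quasi-Poisson, whose AIC is undefined, is reported via
RMSE/MAPE only — and then produces the winner's IRR curves, weekly PAF
series and smoothed PAF trends.  A consistency mode forces one lag
specification across all categories, trading a marginal per-category fit
improvement for comparability.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import attribution, effects
from .features import EXPOSURES, LagDesign, build_lag_design
from .gam import CountGAM, ModelScore, default_terms, score
from .synthetic import CATEGORIES, SyntheticDataset, generate_bundle, save_bundle

logger = logging.getLogger("edattrib")

AIC_TIE_TOL = 1e-6


@dataclass(frozen=True)
class CandidateSpec:
    """One candidate model formula: family, max lag, immediate effects."""

    family: str = "poisson"
    max_lag: int = 3
    include_immediate: bool = False

    @property
    def label(self) -> str:
        imm = "imm" if self.include_immediate else "lagged"
        return f"{self.family}-lag{self.max_lag}-{imm}"


def candidate_grid(
    families=("poisson", "negbin"),
    lags=(1, 2, 3),
    immediates=(False,),
) -> list[CandidateSpec]:
    """Candidate grid; defaults to the 6 likelihood-based lag candidates.

    The full sensitivity grid (3 families x 3 lags x 2 immediate flags =
    18 candidates) is ``candidate_grid(("poisson", "quasipoisson",
    "negbin"), (1, 2, 3), (False, True))``.
    """
    return [
        CandidateSpec(f, l, imm)
        for f in families
        for l in lags
        for imm in immediates
    ]


DEFAULT_CONFIG: dict = {
    "n_weeks": 261,
    "start_year": 2014,
    "families": ["poisson", "negbin"],
    "lags": [1, 2, 3],
    "immediates": [False],
    "k_smooth": 8,
    "k_week": 10,
    "k_year": 4,
    "n_grid": 100,
    "paf_mode": "drop-term",
    "paf_span": 0.75,
    "consistency": None,  # e.g. {"max_lag": 3, "include_immediate": False}
    "categories": list(CATEGORIES),
    "irr_lags": None,  # None -> all lags of the winner
}


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


@dataclass
class CandidateResult:
    spec: CandidateSpec
    model: CountGAM
    design: LagDesign
    score: ModelScore


@dataclass
class CategoryResult:
    category: str
    candidates: list
    winner: CandidateResult
    selection_rule: str
    irr_curves: list = field(default_factory=list)
    paf_series: list = field(default_factory=list)
    paf_curves: list = field(default_factory=list)


def fit_candidates(
    admissions: pd.DataFrame,
    exposures: pd.DataFrame,
    candidates: list[CandidateSpec],
    config: dict | None = None,
    category: str | None = None,
) -> list[CandidateResult]:
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out = []
    for spec in candidates:
        design = build_lag_design(
            admissions,
            exposures,
            max_lag=spec.max_lag,
            include_immediate=spec.include_immediate,
            category=category,
        )
        terms = default_terms(
            design, k_smooth=cfg["k_smooth"], k_week=cfg["k_week"], k_year=cfg["k_year"]
        )
        model = CountGAM(terms=terms, family=spec.family).fit(design)
        out.append(CandidateResult(spec, model, design, score(model, design)))
    return out


def select_model(
    candidates: list[CandidateResult], consistency: dict | None = None
) -> tuple[CandidateResult, str]:
    """Winner by AIC among AIC-comparable families; optional consistency override.

    AIC differences below ``AIC_TIE_TOL`` are ties, resolved toward the
    candidate with fewer design columns.
    """
    if consistency:
        forced = [
            c
            for c in candidates
            if c.spec.max_lag == consistency["max_lag"]
            and c.spec.include_immediate == consistency.get("include_immediate", False)
            and c.spec.family != "quasipoisson"
        ]
        if not forced:
            raise ValueError("no candidate matches the consistency specification")
        winner = min(forced, key=lambda c: (c.score.aic, c.model.n_coef_))
        return winner, "consistency"
    scored = [c for c in candidates if c.score.aic is not None]
    if not scored:
        raise ValueError("no AIC-comparable candidate (all quasi-Poisson?)")
    best_aic = min(c.score.aic for c in scored)
    tied = [c for c in scored if c.score.aic - best_aic < AIC_TIE_TOL]
    winner = min(tied, key=lambda c: c.model.n_coef_)
    return winner, "aic"


def run_category(
    category: str,
    admissions: pd.DataFrame,
    exposures: pd.DataFrame,
    config: dict | None = None,
) -> CategoryResult:
    """Full per-category protocol: grid fit, selection, IRR and PAF products."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    cands = candidate_grid(tuple(cfg["families"]), tuple(cfg["lags"]), tuple(cfg["immediates"]))
    t0 = time.time()
    results = fit_candidates(admissions, exposures, cands, cfg, category=category)
    winner, rule = select_model(results, cfg.get("consistency"))
    logger.info(
        "%s: winner %s (rule=%s) in %.1fs", category, winner.spec.label, rule, time.time() - t0
    )

    design, model = winner.design, winner.model
    lags = cfg["irr_lags"] or list(range(1, winner.spec.max_lag + 1))
    irr_curves, paf_list, paf_curves = [], [], []
    for exposure in design.exposure_names:
        for lag in lags:
            irr_curves.append(
                effects.irr_curve(model, design, exposure, lag, n_grid=cfg["n_grid"])
            )
            ps = attribution.paf_series(model, design, exposure, lag, mode=cfg["paf_mode"])
            paf_list.append(ps)
            paf_curves.append(
                attribution.smooth_paf(ps, design, span=cfg["paf_span"], n_grid=cfg["n_grid"])
            )
    return CategoryResult(
        category=category,
        candidates=results,
        winner=winner,
        selection_rule=rule,
        irr_curves=irr_curves,
        paf_series=paf_list,
        paf_curves=paf_curves,
    )


def summarize_shares(totals) -> pd.DataFrame:
    """Per-category share of total admissions, in percent.

    ``totals`` maps category -> total admissions (dict or Series).  The
    rounded column reproduces printed-style integer percentages; the
    unrounded share is retained.
    """
    s = pd.Series(totals, dtype=float)
    if len(s) == 0 or (s < 0).any():
        raise ValueError("totals must be non-negative and non-empty")
    grand = s.sum()
    if grand <= 0:
        raise ValueError("grand total must be positive")
    share = s / grand * 100.0
    return pd.DataFrame(
        {"total": s, "share_pct": share, "share_pct_rounded": share.round(0).astype(int)}
    )


# ---------------------------------------------------------------------------
# study bundle runner
# ---------------------------------------------------------------------------


def run_all(
    config: dict | None = None,
    seed: int = 0,
    outdir=None,
    dataset: SyntheticDataset | None = None,
    make_figures: bool = True,
) -> dict:
    """Run the whole study over all categories; write CSV/figure artifacts.

    Per-category failures are isolated: the category is reported in the
    summary with its error and the remaining categories still complete.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    stamp = {"config_hash": config_hash(cfg), "seed": seed}
    if dataset is None:
        dataset = generate_bundle(n_weeks=cfg["n_weeks"], seed=seed, categories=tuple(cfg["categories"]))
    out = pathlib.Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        save_bundle(dataset, out / "data")

    results, failures = {}, {}
    t_start = time.time()
    for cat in cfg["categories"]:
        try:
            adm = dataset.admissions_for(cat)
            results[cat] = run_category(cat, adm, dataset.exposures, cfg)
        except Exception as exc:  # isolate per-category failures
            logger.exception("category %s failed", cat)
            failures[cat] = repr(exc)

    selection_rows, irr_frames, paf_frames, curve_frames = [], [], [], []
    for cat, res in results.items():
        for cand in res.candidates:
            selection_rows.append(
                {
                    "category": cat,
                    "candidate": cand.spec.label,
                    "family": cand.spec.family,
                    "max_lag": cand.spec.max_lag,
                    "include_immediate": cand.spec.include_immediate,
                    "aic": cand.score.aic,
                    "rmse": cand.score.rmse,
                    "mape": cand.score.mape,
                    "winner": cand is res.winner,
                    "selection_rule": res.selection_rule,
                    **stamp,
                }
            )
        irr_frames += [c.to_frame() for c in res.irr_curves]
        curve_frames += [c.to_frame() for c in res.paf_curves]
        for ps in res.paf_series:
            f = ps.frame.copy()
            f.insert(0, "category", cat)
            f.insert(1, "exposure", ps.exposure)
            f.insert(2, "lag", ps.lag)
            paf_frames.append(f)

    bundle = {
        "results": results,
        "failures": failures,
        "selection_report": pd.DataFrame(selection_rows),
        "irr_curves": pd.concat(irr_frames, ignore_index=True) if irr_frames else pd.DataFrame(),
        "paf_series": pd.concat(paf_frames, ignore_index=True) if paf_frames else pd.DataFrame(),
        "paf_curves": pd.concat(curve_frames, ignore_index=True) if curve_frames else pd.DataFrame(),
        "stamp": stamp,
        "runtime_s": time.time() - t_start,
    }
    totals = dataset.admissions.groupby("category")["count"].sum()
    bundle["shares"] = (
        summarize_shares(totals)
        if len(totals)
        else pd.DataFrame(columns=["total", "share_pct", "share_pct_rounded"])
    )

    if out is not None:
        bundle["selection_report"].to_csv(out / "selection_report.csv", index=False)
        bundle["irr_curves"].to_csv(out / "irr_curves.csv", index=False)
        bundle["paf_series"].to_csv(out / "paf_series.csv", index=False)
        bundle["paf_curves"].to_csv(out / "paf_curves.csv", index=False)
        bundle["shares"].to_csv(out / "shares.csv")
        with open(out / "run_summary.json", "w") as fh:
            json.dump(
                {**stamp, "runtime_s": bundle["runtime_s"], "failures": failures,
                 "categories_done": sorted(results)},
                fh,
                indent=2,
            )
        if make_figures and results:
            figures(bundle, out / "figures")
    if not cfg["categories"]:
        logger.warning("empty category list: nothing to do")
    return bundle


def figures(bundle: dict, outdir) -> list:
    """IRR panels per category and grouped PAF-trend panels per exposure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for cat, res in bundle["results"].items():
        curves = res.irr_curves
        if not curves:
            continue
        ncol = res.winner.spec.max_lag
        nrow = len(res.design_exposures) if hasattr(res, "design_exposures") else len(
            res.winner.design.exposure_names
        )
        fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.2 * nrow), squeeze=False)
        by_key = {(c.exposure, c.lag): c for c in curves}
        for i, exp_name in enumerate(res.winner.design.exposure_names):
            for j in range(ncol):
                ax = axes[i][j]
                c = by_key.get((exp_name, j + 1))
                if c is None:
                    ax.axis("off")
                    continue
                sig = effects.significance_mask(c)
                ax.fill_between(c.grid, c.lo, c.hi, alpha=0.25, color="tab:blue")
                ax.plot(c.grid, c.irr, color="black", lw=1)
                ax.axhline(1.0, color="grey", lw=0.5)
                ax.axvline(c.reference, color="tab:orange", lw=0.8)
                if sig.any():
                    ax.scatter(c.grid[sig], c.irr[sig], s=4, color="tab:blue")
                ax.set_title(f"{exp_name} lag {j + 1}", fontsize=7)
        fig.suptitle(f"IRR — {cat}", fontsize=10)
        fig.tight_layout()
        path = out / f"irr_{cat.replace(' ', '_').replace('/', '-')}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)

    # grouped PAF trends: one figure per exposure, panels by lag, lines by category
    all_curves = [c for res in bundle["results"].values() for c in res.paf_curves]
    groups = sorted({c.group for c in all_curves if c.group})
    for grp in groups:
        for exposure in EXPOSURES:
            sel = [c for c in all_curves if c.group == grp and c.exposure == exposure]
            if not sel:
                continue
            lags = sorted({c.lag for c in sel})
            fig, axes = plt.subplots(1, len(lags), figsize=(3.2 * len(lags), 2.6), squeeze=False)
            for j, lag in enumerate(lags):
                ax = axes[0][j]
                for c in [s for s in sel if s.lag == lag]:
                    ax.fill_between(c.grid, c.lo, c.hi, alpha=0.15)
                    ax.plot(c.grid, c.trend, lw=1, label=c.category)
                ax.axhline(0.0, color="grey", lw=0.5)
                ax.set_title(f"{exposure} lag {lag}", fontsize=7)
            axes[0][0].legend(fontsize=5)
            fig.suptitle(f"PAF trend — {grp}", fontsize=9)
            fig.tight_layout()
            path = out / f"paf_{grp.split()[0].lower()}_{exposure}.png"
            fig.savefig(path, dpi=100)
            plt.close(fig)
            written.append(path)
    return written
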