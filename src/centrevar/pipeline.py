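"""End-to-end profiling pipeline: simulate/load -> filter -> impute ->
fit -> profile -> report.

For each of the m imputed datasets the pipeline fits unadjusted and
case-mix-adjusted random-intercept models for in-hospital mortality
(binary) and discharge CPC (ordinal), a mixed linear model for time to
ALS and a mixed logistic model for RRS reporting, then pools across
imputations (Rubin's rules for coefficients and centre effects; the
random-intercept SD tau on the log scale by default) and derives the
median odds ratio, rankability and Nagelkerke R^2. Structure-of-care
indicators are compared on observed CPC scores with a Monte-Carlo Fisher
exact test after collapsing CPC 4 (vegetative state) and 5 (dead).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .config import PipelineConfig
from .descriptives import compare_groups, fisher_exact_rxc
from .glmm import CentreEffects, InputError, ModelSpec, adjusted_effect, \
    fit_fixed, fit_mixed
from .impute import impute, pool_scalar
from .metrics import build_caterpillar, median_odds_ratio, nagelkerke_r2, \
    percent_change_mor, rankability
from .report import ProfileReport
from .simulate import generate_cohort, inject_missingness

logger = logging.getLogger("centrevar")

DESCRIPTIVE_VARIABLES = [
    "age", "charlson", "time_to_als", "sex", "pre_mrs", "pre_cpc",
    "rrs_reported", "witnessed", "weekend", "shift", "shockable", "location",
]


class RrsOutcomeUnavailable(InputError):
    """The RRS -> outcome effect cannot be estimated from arrest-only data."""


def rrs_effect_on_outcome(*_args, **_kwargs):
    """Deliberately refused analysis.

    RRS reporting is assumed to act on outcomes by *preventing* cardiac
    arrest; a cohort that only samples patients who already arrested
    carries no control group, so the effect is not identifiable here.
    """
    raise RrsOutcomeUnavailable(
        "The effect of RRS reporting on outcome cannot be estimated from an "
        "arrest-only cohort: RRS acts by preventing arrest and the design "
        "has no non-arrest control group."
    )


def filter_centres(cohort: pd.DataFrame, centres: pd.DataFrame,
                   threshold: int = 10):
    """Drop centres contributing ``<= threshold`` patients.

    Returns ``(cohort, centres, excluded)`` with ``excluded`` a list of
    ``{"centre_id": ..., "n_patients": ...}`` records.
    """
    counts = cohort["centre_id"].value_counts()
    centres = centres.copy()
    centres["n_patients"] = centres["centre_id"].map(counts).fillna(0).astype(int)
    small = centres[centres["n_patients"] <= threshold]
    excluded = [
        {"centre_id": str(r.centre_id), "n_patients": int(r.n_patients)}
        for r in small.itertuples()
    ]
    keep = set(centres.loc[centres["n_patients"] > threshold, "centre_id"])
    if not keep:
        raise InputError("all centres fall at or below the exclusion threshold")
    for rec in excluded:
        logger.info("excluding centre %s (n=%d <= %d)", rec["centre_id"],
                    rec["n_patients"], threshold)
    cohort_f = cohort[cohort["centre_id"].isin(keep)].reset_index(drop=True)
    centres_f = centres[centres["centre_id"].isin(keep)].reset_index(drop=True)
    return cohort_f, centres_f, excluded


def _pool_tau(taus, scale: str) -> float:
    taus = np.asarray(taus, dtype=float)
    if scale == "log" and np.all(taus > 0):
        return float(np.exp(np.mean(np.log(taus))))
    return float(np.mean(taus))


def _pool_effects(effects_list: list[CentreEffects]) -> CentreEffects:
    """Rubin's rules per centre across imputations."""
    ids = list(effects_list[0].centre_ids)
    for e in effects_list[1:]:
        if list(e.centre_ids) != ids:
            raise InputError("centre sets differ across imputations")
    u = np.array([e.u_hat for e in effects_list])
    v = np.array([e.se_u ** 2 for e in effects_list])
    sf = np.array([e.se_fixed ** 2 for e in effects_list])
    J = u.shape[1]
    u_hat = np.empty(J)
    se_u = np.empty(J)
    for j in range(J):
        pe = pool_scalar(u[:, j], v[:, j])
        u_hat[j], se_u[j] = pe.estimate, pe.se
    return CentreEffects(
        centre_ids=ids, u_hat=u_hat, se_u=se_u,
        se_fixed=np.sqrt(sf.mean(axis=0)),
        n_patients=effects_list[0].n_patients,
    )


def _mixed_over_imputations(completed, spec, nodes):
    fits, effects = [], []
    for d in completed:
        f, e = fit_mixed(spec, d, quadrature_nodes=nodes)
        fits.append(f)
        effects.append(e)
    return fits, effects


def _profile_block(completed, outcome, family, case_mix, cfg,
                   with_r2: bool):
    """Unadjusted + adjusted mixed fits for one logit-scale indicator."""
    nodes = cfg.quadrature_nodes if family == "binary_logit" else None
    spec_u = ModelSpec(outcome, family, [], "centre_id")
    spec_a = ModelSpec(outcome, family, list(case_mix), "centre_id")
    fits_u, eff_u = _mixed_over_imputations(completed, spec_u, nodes)
    fits_a, eff_a = _mixed_over_imputations(completed, spec_a, nodes)
    tau_u = _pool_tau([f.tau for f in fits_u], cfg.pool_tau_scale)
    tau_a = _pool_tau([f.tau for f in fits_a], cfg.pool_tau_scale)
    pooled_u = _pool_effects(eff_u)
    pooled_a = _pool_effects(eff_a)
    mor_u = median_odds_ratio(tau_u)
    mor_a = median_odds_ratio(tau_a)
    r2 = None
    if with_r2:
        r2s = []
        for d in completed:
            ff = fit_fixed(ModelSpec(outcome, family, list(case_mix)), d)
            r2s.append(nagelkerke_r2(ff.loglik_null, ff.loglik, ff.n_obs))
        r2 = float(np.mean(r2s))
    block = {
        "tau_unadjusted": tau_u,
        "tau_adjusted": tau_a,
        "mor_unadjusted": mor_u,
        "mor_adjusted": mor_a,
        "pct_decrease_mor": percent_change_mor(max(mor_u, 1.0),
                                               max(mor_a, 1.0)),
        "rankability": rankability(tau_a, pooled_a.se_fixed,
                                   aggregate=cfg.se_aggregate),
        "caterpillar": build_caterpillar(pooled_u, pooled_a),
        "converged": bool(all(f.converged for f in fits_u + fits_a)),
    }
    if r2 is not None:
        block["nagelkerke_r2"] = r2
    adj_fits = fits_a
    return block, adj_fits


def _pooled_coefficients(fits, case_mix, alpha):
    """Rubin-pooled case-mix coefficients (as odds ratios) from mixed fits."""
    out = {}
    names = [k for k in fits[0].beta if k != "intercept"]
    for name in names:
        est = np.array([f.beta[name] for f in fits])
        var = np.array([f.beta_se[name] ** 2 for f in fits])
        pe = pool_scalar(est, var)
        lo, hi = pe.ci(alpha)
        out[name] = {
            "estimate": pe.estimate, "se": pe.se,
            "odds_ratio": float(np.exp(pe.estimate)),
            "ci_lower": float(np.exp(lo)), "ci_upper": float(np.exp(hi)),
        }
    return out


def _structure_tables(cohort, centres, collapse_45=True):
    """CPC-by-indicator contingency tables on observed CPC scores."""
    merged = cohort.merge(centres, on="centre_id", how="left")
    merged = merged[merged["cpc_discharge"].notna()]
    cpc = merged["cpc_discharge"].astype(int)
    if collapse_45:
        cpc = cpc.clip(upper=4)  # 4 now means "vegetative state or dead"
    tables = {}
    for ind in ("training_twice_yearly", "intensivist_24_7",
                "als_physician_24_7"):
        if merged[ind].nunique() < 2:
            tables[ind] = None
            continue
        ct = pd.crosstab(cpc, merged[ind])
        tables[ind] = ct.to_numpy()
    return tables


def run_profile(config: PipelineConfig, write: bool = True):
    """Execute the full profiling analysis; returns the report dict.

    With ``write=True`` the report JSON, tables and (optionally) figures
    are also written under ``config.out_dir``.
    """
    seeds = np.random.SeedSequence(config.seed).generate_state(4)
    seeds = [int(s) % (2 ** 31) for s in seeds]
    errors: dict[str, str] = {}

    # --- load or simulate -------------------------------------------------
    if config.cohort_path:
        cohort_raw = io.read_cohort(config.cohort_path)
        centres = io.read_centres(config.centres_path)
        truth = None
    else:
        sim = config.sim.model_copy(update={"seed": seeds[0]})
        complete, centres, truth = generate_cohort(sim)
        cohort_raw = inject_missingness(complete, sim)
    logger.info("cohort: %d patients, %d centres", len(cohort_raw),
                cohort_raw["centre_id"].nunique())

    # --- centre exclusion -------------------------------------------------
    cohort, centres, excluded = filter_centres(
        cohort_raw, centres, config.min_patients_per_centre
    )
    n_excluded = int(sum(e["n_patients"] for e in excluded))

    # --- imputation or complete case --------------------------------------
    if config.complete_case:
        cc = cohort.dropna().reset_index(drop=True)
        completed = [cc, cc.copy()]
        m_used = 1
    else:
        imp = impute(cohort, m=config.m_imputations, seed=seeds[1],
                     n_iter=config.mice_iterations)
        completed = imp.completed
        m_used = imp.m

    # --- outcome indicators -----------------------------------------------
    outcomes: dict[str, dict] = {}
    case_mix_effects: dict[str, dict] = {}
    for key, outcome, family in (
        ("mortality", "mortality", "binary_logit"),
        ("cpc", "cpc_discharge", "ordinal_logit"),
    ):
        try:
            block, adj_fits = _profile_block(
                completed, outcome, family, config.case_mix, config,
                with_r2=True,
            )
            outcomes[key] = block
            case_mix_effects[key] = _pooled_coefficients(
                adj_fits, config.case_mix, config.alpha
            )
        except Exception as exc:  # recorded, pipeline continues
            logger.warning("outcome block %s failed: %s", key, exc)
            errors[f"outcome:{key}"] = str(exc)

    # --- process indicators -----------------------------------------------
    process: dict[str, dict] = {}
    try:
        spec_u = ModelSpec("time_to_als", "gaussian", [], "centre_id")
        spec_a = ModelSpec("time_to_als", "gaussian", list(config.case_mix),
                           "centre_id")
        fits_u, eff_u = _mixed_over_imputations(completed, spec_u, None)
        fits_a, eff_a = _mixed_over_imputations(completed, spec_a, None)
        tau_u = _pool_tau([f.tau for f in fits_u], config.pool_tau_scale)
        tau_a = _pool_tau([f.tau for f in fits_a], config.pool_tau_scale)
        pooled_a = _pool_effects(eff_a)
        process["time_to_als"] = {
            "tau_unadjusted": tau_u, "tau_adjusted": tau_a,
            "rankability": rankability(tau_a, pooled_a.se_fixed,
                                       aggregate=config.se_aggregate),
            "caterpillar": build_caterpillar(_pool_effects(eff_u), pooled_a),
            "converged": bool(all(f.converged for f in fits_u + fits_a)),
        }
    except Exception as exc:
        logger.warning("time-to-ALS block failed: %s", exc)
        errors["process:time_to_als"] = str(exc)
    try:
        block, _ = _profile_block(completed, "rrs_reported", "binary_logit",
                                  config.case_mix, config, with_r2=False)
        block.pop("nagelkerke_r2", None)
        block.pop("pct_decrease_mor", None)
        process["rrs_reported"] = {
            "tau_unadjusted": block["tau_unadjusted"],
            "tau_adjusted": block["tau_adjusted"],
            "mor_adjusted": block["mor_adjusted"],
            "rankability": block["rankability"],
            "caterpillar": block["caterpillar"],
            "converged": block["converged"],
        }
    except Exception as exc:
        logger.warning("RRS block failed: %s", exc)
        errors["process:rrs_reported"] = str(exc)

    # --- back-door-adjusted effect of time to ALS on CPC --------------------
    als_effect = None
    try:
        ors, los, his = [], [], []
        for d in completed:
            fit = adjusted_effect(
                ModelSpec("cpc_discharge", "ordinal_logit", ["time_to_als"]),
                d, list(config.als_adjustment_set),
            )
            est = fit.beta["time_to_als"]
            var = fit.beta_se["time_to_als"] ** 2
            ors.append(est)
            los.append(var)
        pe = pool_scalar(np.array(ors), np.array(los))
        lo, hi = pe.ci(config.alpha)
        als_effect = {
            "exposure": "time_to_als", "outcome": "cpc_discharge",
            "odds_ratio": float(np.exp(pe.estimate)),
            "ci_lower": float(np.exp(lo)), "ci_upper": float(np.exp(hi)),
            "adjustment_set": list(config.als_adjustment_set),
        }
    except Exception as exc:
        logger.warning("ALS effect block failed: %s", exc)
        errors["effect:time_to_als_on_cpc"] = str(exc)

    # --- structure of care --------------------------------------------------
    structure = []
    tables = _structure_tables(cohort, centres, collapse_45=True)
    for i, (ind, tab) in enumerate(tables.items()):
        if tab is None:
            continue
        p, se = fisher_exact_rxc(tab, n_mc=config.n_mc_fisher,
                                 seed=seeds[2] + i)
        structure.append({
            "indicator": ind, "p_value": p, "mc_se": se, "collapse_45": True,
            "table": [[int(x) for x in row] for row in tab],
        })

    posthoc = None
    try:
        merged0 = completed[0].merge(centres, on="centre_id", how="left")
        merged = [d.merge(centres, on="centre_id", how="left")
                  for d in completed]
        if merged0["training_twice_yearly"].nunique() > 1:
            ests, vars_ = [], []
            for d in merged:
                fit = adjusted_effect(
                    ModelSpec("cpc_discharge", "ordinal_logit",
                              ["training_twice_yearly"]),
                    d, list(config.case_mix),
                )
                ests.append(fit.beta["training_twice_yearly"])
                vars_.append(fit.beta_se["training_twice_yearly"] ** 2)
            pe = pool_scalar(np.array(ests), np.array(vars_))
            lo, hi = pe.ci(config.alpha)
            posthoc = {
                "exposure": "training_twice_yearly", "outcome": "cpc_discharge",
                "odds_ratio": float(np.exp(pe.estimate)),
                "ci_lower": float(np.exp(lo)), "ci_upper": float(np.exp(hi)),
                "adjustment_set": list(config.case_mix),
            }
    except Exception as exc:
        logger.warning("post-hoc training block failed: %s", exc)
        errors["posthoc:training"] = str(exc)

    # --- descriptives -------------------------------------------------------
    descriptives = []
    try:
        comps = compare_groups(cohort, "mortality", DESCRIPTIVE_VARIABLES,
                               n_mc=min(config.n_mc_fisher, 20_000),
                               seed=seeds[3])
        descriptives = [{
            "variable": c.variable, "kind": c.kind, "test": c.test,
            "p_value": c.p_value, "group_stats": c.group_stats,
        } for c in comps]
    except Exception as exc:
        logger.warning("descriptives failed: %s", exc)
        errors["descriptives"] = str(exc)

    n_pat = int(len(cohort))
    surv_n = int((cohort["mortality"] == 0).sum())
    report = {
        "seed": int(config.seed),
        "n_patients": n_pat,
        "n_centres": int(cohort["centre_id"].nunique()),
        "excluded_centres": excluded,
        "n_excluded_patients": n_excluded,
        "survival_n": surv_n,
        "survival_pct": float(round(100.0 * surv_n / n_pat, 1)),
        "missing_cpc_pct": float(
            round(100.0 * cohort["cpc_discharge"].isna().mean(), 1)
        ),
        "m_imputations": int(m_used),
        "complete_case": bool(config.complete_case),
        "outcomes": outcomes,
        "process": process,
        "case_mix_effects": case_mix_effects,
        "als_effect_on_cpc": als_effect,
        "structure": structure,
        "posthoc_training_effect": posthoc,
        "descriptives": descriptives,
        "errors": errors,
    }
    ProfileReport.model_validate(report)  # enforce the shipped contract
    if write:
        write_artifacts(report, config, cohort, centres)
    return report


def write_artifacts(report: dict, config: PipelineConfig,
                    cohort: pd.DataFrame | None = None,
                    centres: pd.DataFrame | None = None) -> Path:
    """Write report JSON (and optional tables/figures) to the output dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_json(report, out / "profile_report.json")
    if cohort is not None:
        io.write_cohort(cohort, out / "cohort.csv")
    if centres is not None:
        io.write_centres(centres, out / "centres.csv")
    for key, block in report.get("outcomes", {}).items():
        rows = []
        for c in block["caterpillar"]["centres"]:
            rows.append({
                "label": c["label"], "rank": c["rank"],
                "n_patients": c["n_patients"],
                "u_unadjusted": c["unadjusted"]["estimate"],
                "u_adjusted": c["adjusted"]["estimate"],
            })
        pd.DataFrame(rows).to_csv(out / f"caterpillar_{key}.csv", index=False)
    if config.make_figures:
        _write_figures(report, out)
    return out


def _write_figures(report: dict, out: Path) -> None:
    import matplotlib
    matplotlib.use("svg")
    import matplotlib.pyplot as plt

    panels = list(report.get("outcomes", {}).items()) + \
        list(report.get("process", {}).items())
    for key, block in panels:
        cats = block["caterpillar"]["centres"]
        fig, ax = plt.subplots(figsize=(6, 4))
        xs = np.arange(len(cats))
        for off, which, color in ((-0.15, "unadjusted", "C0"),
                                  (0.15, "adjusted", "C1")):
            est = [c[which]["estimate"] for c in cats]
            lo = [c[which]["lower"] for c in cats]
            hi = [c[which]["upper"] for c in cats]
            ax.errorbar(xs + off, est,
                        yerr=[np.subtract(est, lo), np.subtract(hi, est)],
                        fmt="o", ms=3, color=color, label=which)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xticks(xs, [c["label"] for c in cats], rotation=90, fontsize=6)
        ax.set_ylabel("centre effect")
        ax.set_title(key)
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / f"caterpillar_{key}.svg")
        plt.close(fig)

    for st in report.get("structure", []):
        tab = np.asarray(st["table"], dtype=float)
        fig, ax = plt.subplots(figsize=(4, 3))
        frac = tab / tab.sum(axis=0, keepdims=True)
        bottoms = np.zeros(tab.shape[1])
        for k in range(tab.shape[0]):
            ax.bar(range(tab.shape[1]), frac[k], bottom=bottoms,
                   label=f"CPC {k}" + ("+5" if k == 4 else ""))
            bottoms += frac[k]
        ax.set_xticks(range(tab.shape[1]), ["no", "yes"])
        ax.set_title(f"{st['indicator']} (p={st['p_value']:.3g})")
        ax.legend(fontsize=6)
        fig.tight_layout()
        fig.savefig(out / f"structure_{st['indicator']}.svg")
        plt.close(fig)
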