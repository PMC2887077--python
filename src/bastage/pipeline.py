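"""End-to-end molecular staging run.

Order of stages, mirroring how the method is applied to a cohort:

1. histology differential scoring -> seed groups (|differential| >= 2);
2. signature derivation between the seed groups (median normalization,
   fold-change filter, Welch t, BH-FDR);
3. nearest-shrunken-centroid shrinkage selection and ten-times ten-fold
   CV with >= 6/10 majority voting, assigning both seed (out-of-fold,
   allowing reclassification) and mixed-histology samples;
4. clinical association of the molecular groups: Fisher tests on
   categorical covariates, Wilcoxon on age, odds ratio for the two-year
   outcome, Kaplan-Meier + log-rank transplant-free survival, and
   logistic outcome ~ age (+ group) models.

Every output is reproducible from the config (including its seed); a
run log records the filter trail and all assignments.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import lifelines
import numpy as np
import pandas as pd
import scipy
import statsmodels

from . import __version__, clinical, io, nsc
from .histology import (
    FIBROSIS,
    INFLAMMATION,
    assign_histology_groups,
    groups_to_frame,
    scores_from_table,
)
from .signature import SignatureResult, derive_signature

logger = logging.getLogger("bastage.pipeline")


class PipelineError(ValueError):
    """Inconsistent pipeline inputs."""


@dataclass(frozen=True)
class PipelineResult:
    histology_groups: pd.DataFrame
    signature: SignatureResult
    chosen_delta: float
    cv_error_curve: pd.Series
    votes: nsc.VoteTable
    molecular_groups: pd.Series
    associations: pd.DataFrame
    km_curves: pd.DataFrame
    output_files: dict[str, Path]


def _check_ids(expression: pd.DataFrame, samples: pd.DataFrame) -> None:
    mat_ids = set(map(str, expression.columns))
    tab_ids = set(samples["sample_id"])
    if mat_ids != tab_ids:
        only_mat = sorted(mat_ids - tab_ids)
        only_tab = sorted(tab_ids - mat_ids)
        raise PipelineError(
            "sample IDs differ between expression matrix and sample table; "
            f"matrix-only: {only_mat}, table-only: {only_tab}"
        )


def _associations(
    samples: pd.DataFrame, groups: pd.Series, censor_months: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Association report + KM curves for classified samples only."""
    meta = samples.set_index("sample_id")
    classified = groups[groups != nsc.UNCLASSIFIED]
    meta = meta.loc[classified.index]
    infl = classified == INFLAMMATION
    rows = []

    ages_i = meta.loc[infl, "age_days"].dropna()
    ages_f = meta.loc[~infl, "age_days"].dropna()
    if len(ages_i) and len(ages_f):
        res = clinical.wilcoxon_rank_sum(ages_i, ages_f, continuity=True)
        rows.append(("age_days", "wilcoxon_rank_sum", res.statistic, res.p,
                     f"median {ages_i.median():.1f} vs {ages_f.median():.1f} days"))
        p_centers = clinical.compare_age_centers(ages_i, ages_f, method="wilcoxon")
        rows.append(("age_center", "gaussian_kde_centers", float("nan"), p_centers,
                     "center equality via rank-sum on KDE-compared distributions"))

    def binary_2x2(col: str, positive) -> None:
        sub = meta[col].dropna()
        tab = np.array(
            [
                [(sub[infl.reindex(sub.index)] == positive).sum(),
                 (sub[infl.reindex(sub.index)] != positive).sum()],
                [(sub[~infl.reindex(sub.index)] == positive).sum(),
                 (sub[~infl.reindex(sub.index)] != positive).sum()],
            ]
        )
        if tab.sum() == 0:
            return
        p = clinical.fisher_exact_2x2(tab)
        rows.append((col, "fisher_exact", float("nan"), p, f"table={tab.tolist()}"))

    binary_2x2("sex", "female")
    binary_2x2("clinical_type", "BASM")
    binary_2x2("cholangitis", 1)
    binary_2x2("ascites", 1)

    # two-year outcome: rows = group (fibrosis first), cols = (event, no event)
    ev = meta["event"].astype(int)
    outcome_tab = np.array(
        [
            [int(ev[~infl].sum()), int((1 - ev[~infl]).sum())],
            [int(ev[infl].sum()), int((1 - ev[infl]).sum())],
        ]
    )
    p_outcome = clinical.fisher_exact_2x2(outcome_tab)
    rows.append(("event_2y", "fisher_exact", float("nan"), p_outcome,
                 f"table={outcome_tab.tolist()}"))
    try:
        orr = clinical.odds_ratio_ci(outcome_tab, method="conditional_exact")
        rows.append(
            ("event_2y", "odds_ratio_conditional_exact", orr.odds_ratio, p_outcome,
             f"OR={orr.odds_ratio:.3g} (95% CI {orr.ci_low:.3g}-{orr.ci_high:.3g}), "
             "fibrosis vs inflammation")
        )
    except clinical.ClinicalStatsError as exc:
        logger.warning("odds ratio unavailable: %s", exc)

    times = meta["followup_months"].clip(upper=censor_months)
    events = (ev == 1) & (meta["followup_months"] <= censor_months)
    lr = clinical.logrank_test(times, events.astype(int), classified.loc[meta.index])
    rows.append(("transplant_free_survival", "logrank", lr.chi2, lr.p,
                 "inflammation vs fibrosis"))

    km_frames = []
    for label in (INFLAMMATION, FIBROSIS):
        mask = classified.loc[meta.index] == label
        if mask.sum() == 0:
            continue
        curve = clinical.km_estimate(times[mask], events[mask].astype(int))
        frame = curve.to_frame()
        frame.insert(0, "group", label)
        km_frames.append(frame)
    km = pd.concat(km_frames, ignore_index=True) if km_frames else pd.DataFrame()

    # logistic models: outcome ~ age, then outcome ~ age + group
    age = meta["age_days"].to_numpy(dtype=float)
    ok = np.isfinite(age)
    y = ev.to_numpy(dtype=float)[ok]
    if 0 < y.sum() < y.size:
        age_c = age[ok] - age[ok].mean()
        X1 = np.column_stack([np.ones(int(ok.sum())), age_c])
        fit1 = clinical.logistic_fit(y, X1, names=("intercept", "age_days"))
        rows.append(("event_2y~age", "logistic_regression", fit1.coefficients[1],
                     fit1.p_values[1],
                     f"age slope per day, converged={fit1.converged}"))
        grp = (classified.loc[meta.index].to_numpy() == FIBROSIS).astype(float)[ok]
        X2 = np.column_stack([np.ones(int(ok.sum())), age_c, grp])
        fit2 = clinical.logistic_fit(
            y, X2, names=("intercept", "age_days", "fibrosis")
        )
        rows.append(("event_2y~age+group", "logistic_regression",
                     fit2.coefficients[2], fit2.p_values[2],
                     f"fibrosis-group effect adjusted for age, "
                     f"converged={fit2.converged}"))
    else:
        logger.warning("logistic models skipped: outcome has no variation")

    report = pd.DataFrame(
        rows, columns=["variable", "test", "statistic", "p", "detail"]
    )
    return report, km


def run_pipeline(config: io.PipelineConfig) -> PipelineResult:
    """Execute the full staging workflow and write the result bundle.

    Writes, under ``config.output_dir``: ``histology_groups.csv``,
    ``signature.tsv`` + ``signature_trail.json``, ``votes.csv``,
    ``associations.tsv``, ``km_curves.tsv`` and ``run_log.txt``.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log_path = out_dir / "run_log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("bastage")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info(
            "bastage %s | python %s | numpy %s scipy %s pandas %s "
            "statsmodels %s lifelines %s",
            __version__, platform.python_version(), np.__version__,
            scipy.__version__, pd.__version__, statsmodels.__version__,
            lifelines.__version__,
        )
        logger.info("seed=%d config=%s", config.rng_seed, config)

        expression = io.read_expression_tsv(config.expression_tsv)
        samples = io.read_sample_table(config.sample_csv)
        _check_ids(expression, samples)

        # 1. histology groups
        scores = scores_from_table(samples)
        groups, counts = assign_histology_groups(scores, config.histology_threshold)
        hist_frame = groups_to_frame(groups)
        logger.info(
            "histology threshold %d: %d inflammation, %d fibrosis, %d mixed",
            config.histology_threshold, *counts,
        )
        label_of = hist_frame.set_index("subject_id")["label"]
        seed_ids = {
            INFLAMMATION: list(label_of.index[label_of == INFLAMMATION]),
            FIBROSIS: list(label_of.index[label_of == FIBROSIS]),
        }
        if min(len(v) for v in seed_ids.values()) < 2:
            raise PipelineError(
                "histology seed groups too small for signature derivation: "
                f"{ {k: len(v) for k, v in seed_ids.items()} }"
            )

        # 2. signature
        sig = derive_signature(
            expression, seed_ids,
            fc_threshold=config.fc_threshold, alpha=config.alpha, fdr=config.fdr,
        )
        probe_ids = sig.probe_ids
        if len(probe_ids) < 2:
            raise PipelineError(
                f"signature retained {len(probe_ids)} probes; cannot classify"
            )

        # 3. NSC with repeated CV voting
        seed_samples = seed_ids[INFLAMMATION] + seed_ids[FIBROSIS]
        train = expression.loc[probe_ids, seed_samples]
        train_labels = label_of.loc[seed_samples]
        chosen_delta, curve = nsc.select_delta(
            train, train_labels, config.delta_grid, folds=config.folds,
            seed=config.rng_seed, priors=config.priors, m_variant=config.m_variant,
        )
        logger.info("chosen shrinkage delta = %g (CV error %s)",
                    chosen_delta, curve.to_dict())
        external_ids = [s for s in expression.columns if s not in set(seed_samples)]
        votes = nsc.repeated_cv_classify(
            train, train_labels,
            external_matrix=expression.loc[probe_ids, external_ids],
            repetitions=config.repetitions, folds=config.folds,
            seed=config.rng_seed, delta=chosen_delta, priors=config.priors,
            m_variant=config.m_variant, vote_threshold=config.vote_threshold,
            external_mode=config.external_vote_mode,
        )
        molecular = votes.assignments.reindex(expression.columns)
        n_assigned = int((molecular != nsc.UNCLASSIFIED).sum())
        logger.info(
            "molecular assignment: %d/%d samples assigned (%s)",
            n_assigned, len(molecular),
            molecular.value_counts().to_dict(),
        )

        # 4. clinical association
        associations, km = _associations(samples, molecular, config.censor_months)
        for row in associations.itertuples(index=False):
            logger.info("association %s [%s]: p=%.4g (%s)",
                        row.variable, row.test, row.p, row.detail)

        files = {
            "histology_groups": out_dir / "histology_groups.csv",
            "signature": out_dir / "signature.tsv",
            "signature_trail": out_dir / "signature_trail.json",
            "votes": out_dir / "votes.csv",
            "associations": out_dir / "associations.tsv",
            "km_curves": out_dir / "km_curves.tsv",
            "run_log": log_path,
        }
        hist_frame.to_csv(files["histology_groups"], index=False)
        sig.table.to_csv(files["signature"], sep="\t")
        files["signature_trail"].write_text(json.dumps(
            {
                "n_input": sig.trail.n_input,
                "n_after_fc": sig.trail.n_after_fc,
                "n_after_fdr": sig.trail.n_after_fdr,
                "chosen_delta": chosen_delta,
                "seed": config.rng_seed,
            },
            indent=2,
        ))
        votes.to_csv(files["votes"])
        associations.to_csv(files["associations"], sep="\t", index=False)
        km.to_csv(files["km_curves"], sep="\t", index=False)
    finally:
        root.removeHandler(handler)
        handler.close()

    return PipelineResult(
        histology_groups=hist_frame,
        signature=sig,
        chosen_delta=chosen_delta,
        cv_error_curve=curve,
        votes=votes,
        molecular_groups=molecular,
        associations=associations,
        km_curves=km,
        output_files=files,
    )
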