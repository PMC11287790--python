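"""End-to-end synthetic-study driver.

Generates a study with the configured arousal phenotype (the drug that
raises catecholaminergic tone improves d' and the CPP while inverting the
frontal accuracy x confidence interaction), runs every analysis stage, and
assembles one JSON-serializable summary: drug effects on d'/meta-d'/M-diff
and confidence, pupil-bin polynomial fits, hierarchical M-ratio
posteriors, CPP/FP cluster statistics, and cross-task decoding clusters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import decoding, erp, hierarchical, pupil, sdt
from .stats import BfConfig, rm_anova, t_test
from .synthetic import (
    DRUGS,
    EpochGenConfig,
    SessionConfig,
    StudyBundle,
    StudyConfig,
    make_study,
    simulate_epochs,
)

logger = logging.getLogger(__name__)

__all__ = ["ReportConfig", "run_report"]


def _default_study() -> StudyConfig:
    return StudyConfig(
        n_subjects=27,
        n_trials=400,
        epochs=EpochGenConfig(
            sfreq=128.0,
            window=(-0.7, 1.55),
            cpp_gain={
                "base": 4.0, "accuracy_term": 1.5, "confidence_term": 1.0,
                "drug_term": {"PLC": 0.0, "DNP": 0.0, "ATX": 1.5},
            },
            fp_gain={
                "base": -2.0,
                "kappa": {"PLC": 1.5, "DNP": 1.5, "ATX": -1.5},
                "drug_term": {"PLC": 0.0, "DNP": -0.5, "ATX": -0.8},
            },
            pattern_snr=0.8,
            pattern_window=(0.15, 0.8),
            pattern_follows="response",
            noise_ar=0.9,
        ),
    )


@dataclass
class ReportConfig:
    """Study scale and analysis settings for the end-to-end run.

    Defaults are a reduced-size but statistically faithful rendering of
    the study design (27 subjects x 3 sessions; 400 trials per session;
    epochs generated at the 128 Hz analysis rate).
    """

    study: StudyConfig = field(default_factory=_default_study)
    include_erp: bool = True
    include_decoding: bool = True
    include_hierarchical: bool = True
    mcmc_samples: int = 2000
    mcmc_warmup: int = 500
    n_perm: int = 512
    localizer_trials: int = 160
    decode_train_window: tuple[float, float] = (0.0, 0.75)
    decode_test_window: tuple[float, float] = (0.0, 1.0)
    response_window: tuple[float, float] = (-0.8, 0.1)
    analysis_window: tuple[float, float] = (-0.6, 0.0)


def _drug_tests(metrics: pd.DataFrame) -> dict:
    """Pairwise drug-vs-placebo behavioral tests in the study's style."""
    wide = {m: metrics.pivot(index="subject", columns="drug", values=m)
            for m in ("d_prime", "meta_d", "m_diff", "conf_rate", "criterion")}
    out = {}
    for drug in ("ATX", "DNP"):
        res = {}
        # directional prediction for d' (improvement), two-sided elsewhere
        tail = "greater" if drug == "ATX" else "two-sided"
        res["d_prime"] = t_test(
            wide["d_prime"][drug], wide["d_prime"]["PLC"], paired=True,
            tail=tail, bf=BfConfig(sided="one_positive" if tail == "greater" else "two"),
        ).to_dict()
        for m in ("meta_d", "m_diff", "conf_rate", "criterion"):
            res[m] = t_test(
                wide[m][drug], wide[m]["PLC"], paired=True,
                tail="two-sided", bf=BfConfig(),
            ).to_dict()
        out[drug] = res
    return out


def _subject_metrics(bundle: StudyBundle) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    rows, kept = [], []
    excl_totals = None
    for subj in sorted(bundle.trials["subject"].unique()):
        for drug in bundle.config.drugs:
            tab = bundle.session_trials(subj, drug)
            filtered, rep = sdt.exclude_trials(tab)
            kept.append(filtered)
            m = sdt.subject_metrics(filtered)
            m.update(subject=subj, drug=drug)
            rows.append(m)
            if excl_totals is None:
                excl_totals = rep.to_dict()
            else:
                excl_totals = {k: excl_totals[k] + v for k, v in rep.to_dict().items()}
    return pd.DataFrame(rows), pd.concat(kept, ignore_index=True), excl_totals


def _pupil_section(filtered: pd.DataFrame) -> dict:
    binned = pupil.assign_bins(filtered)
    table = pupil.per_bin_behavior(binned)
    out = {"bin_table_means": table.groupby("bin")[
        ["d_prime", "conf_rate", "meta_d", "m_diff", "mean_pupil_pct"]
    ].mean().to_dict("index")}
    for measure, orders in (("d_prime", (1, 2)), ("conf_rate", (1, 2)),
                            ("meta_d", (1,)), ("m_diff", (1,))):
        for order in orders:
            fits = pupil.fit_bin_polynomials(table, measure, order=order)
            sec = {}
            for coef in [c for c in ("beta1", "beta2") if c in fits]:
                sec[coef] = pupil.group_test(fits, coef).to_dict()
            out[f"{measure}_order{order}"] = sec
    return out, binned


def _erp_section(bundle: StudyBundle, cfg: ReportConfig, seed: int) -> dict:
    drugs = bundle.config.drugs
    cells = [(d, a, c) for d in drugs for a in ("correct", "error")
             for c in ("high", "low")]
    per_subject_cells, per_subject_drug = {"CPP": [], "FP": []}, {"CPP": [], "FP": []}
    times = None
    for subj in sorted(bundle.trials["subject"].unique()):
        roi_cells = {"CPP": [], "FP": []}
        roi_drug = {"CPP": [], "FP": []}
        for drug in drugs:
            ep = bundle.session_epochs(subj, drug)
            ep = erp.baseline_correct(ep)
            ep = erp.response_lock(ep, cfg.response_window)
            ep = erp.downsample(ep, 128.0)
            times = ep.times
            for roi in ("CPP", "FP"):
                tc = erp.roi_average(ep, roi)
                roi_drug[roi].append(tc.mean(axis=0))
                meta = ep.metadata
                for (_, a, c) in [cell for cell in cells if cell[0] == drug]:
                    m = (meta["accuracy"].to_numpy() == a) & (
                        meta["confidence"].to_numpy() == c)
                    roi_cells[roi].append(
                        tc[m].mean(axis=0) if m.any() else np.full(len(times), np.nan)
                    )
        for roi in ("CPP", "FP"):
            per_subject_cells[roi].append(np.stack(roi_cells[roi]))
            per_subject_drug[roi].append(np.stack(roi_drug[roi]))

    sel = (times >= cfg.analysis_window[0]) & (times < cfg.analysis_window[1])
    out = {"times_s": times[sel].tolist()}

    cpp_drug = np.stack(per_subject_drug["CPP"])[:, :, sel]  # subj x drug x time
    i_plc, i_atx = drugs.index("PLC"), drugs.index("ATX")
    res = erp.cluster_test_paired(
        cpp_drug[:, i_atx], cpp_drug[:, i_plc], tail="greater",
        n_perm=cfg.n_perm, seed=seed,
    )
    out["cpp_atx_gt_plc"] = _cluster_dict(res, times[sel])

    fp_cells = np.stack(per_subject_cells["FP"])[:, :, sel]
    idx_plc_atx = [i for i, cell in enumerate(cells) if cell[0] in ("PLC", "ATX")]
    res3 = erp.cluster_rmanova(
        fp_cells[:, idx_plc_atx], {"drug": 2, "accuracy": 2, "confidence": 2},
        [("drug", "accuracy", "confidence")], n_perm=cfg.n_perm, seed=seed + 1,
    )[("drug", "accuracy", "confidence")]
    out["fp_drug_x_accuracy_x_confidence"] = _cluster_dict(res3, times[sel])

    # metacognitive effect per drug in the FP three-way cluster window
    window = _cluster_window(res3, times[sel]) or tuple(cfg.analysis_window)
    me = {}
    for d_i, drug in enumerate(drugs):
        vals = []
        for s in range(len(per_subject_cells["FP"])):
            cellmat = per_subject_cells["FP"][s][:, sel]
            amp = {cells[i][1:]: erp.window_mean(cellmat[i], times[sel], window)
                   for i in range(len(cells)) if cells[i][0] == drug}
            vals.append(erp.metacog_effect(
                amp[("correct", "high")], amp[("correct", "low")],
                amp[("error", "low")], amp[("error", "high")],
            ))
        me[drug] = {"mean": float(np.mean(vals)),
                    "t_vs_0": t_test(vals).to_dict()}
    out["fp_metacog_effect"] = me
    return out


def _cluster_window(res, times) -> tuple[float, float] | None:
    sig = res.significant()
    if not sig:
        return None
    idx = sig[0].indices
    return (float(times[idx.min()]), float(times[idx.max()]) + 1e-9)


def _cluster_dict(res, times) -> dict:
    return {
        "n_clusters": len(res.clusters),
        "min_p": min([c.p_value for c in res.clusters], default=None),
        "significant": [
            {"t_start_s": float(times[c.indices.min()]),
             "t_end_s": float(times[c.indices.max()]),
             "mass": c.mass, "p": c.p_value}
            for c in res.significant()
        ],
    }


def _decoding_section(bundle: StudyBundle, cfg: ReportConfig, seed: int) -> dict:
    study = bundle.config
    loc_cfg = replace(
        study.epochs, pattern_snr=study.epochs.pattern_snr * 1.5,
        pattern_window=(0.07, 0.65), pattern_follows="stimulus",
        window=(-0.1, 0.9),
    )
    subconds = [{"drug": d, "accuracy": a, "confidence": c}
                for d in study.drugs for a in ("correct", "error")
                for c in ("high", "low")]
    gat_all, gat_sub = [], []
    tr_sel = te_sel = None
    for subj in sorted(bundle.trials["subject"].unique()):
        loc_seed = int(np.random.SeedSequence(
            entropy=bundle.seed, spawn_key=(9, int(subj))).generate_state(1)[0] % 2**31)
        loc_trials = bundle.session_trials(subj, "PLC").copy()
        loc_trials = loc_trials.iloc[: cfg.localizer_trials]
        loc = simulate_epochs(loc_trials, loc_cfg, loc_seed)
        main_list = [bundle.session_epochs(subj, d) for d in study.drugs]
        main = erp.EpochSet(
            data=np.concatenate([e.data for e in main_list]),
            times=main_list[0].times, sfreq=main_list[0].sfreq,
            lock="stimulus", channels=main_list[0].channels,
            metadata=pd.concat([e.metadata for e in main_list], ignore_index=True),
        )
        answered = main.metadata["response"].ne("none").to_numpy()
        main = erp.EpochSet(main.data[answered], main.times, main.sfreq,
                            "stimulus", main.channels,
                            main.metadata.loc[answered].reset_index(drop=True))
        tr_sel = (loc.times >= cfg.decode_train_window[0]) & (
            loc.times < cfg.decode_train_window[1])
        te_sel = (main.times >= cfg.decode_test_window[0]) & (
            main.times < cfg.decode_test_window[1])
        loc_c = loc.copy_with(data=loc.data[:, :, tr_sel], times=loc.times[tr_sel])
        main_c = main.copy_with(data=main.data[:, :, te_sel], times=main.times[te_sel])
        mats = decoding.gat_cross(
            loc_c, main_c, subconditions=[{"all": None}] + subconds,
            seed=seed + int(subj),
        )
        gat_all.append(mats["all"])
        gat_sub.append({k: v for k, v in mats.items() if k != "all"})

    gat_all = np.stack(gat_all)
    res = decoding.cluster_test_gat(gat_all, n_perm=cfg.n_perm, seed=seed)
    out = {
        "mean_auc_all": float(np.nanmean(gat_all)),
        "cluster": {
            "n_clusters": len(res.clusters),
            "min_p": min([c.p_value for c in res.clusters], default=None),
            "n_significant": len(res.significant()),
        },
    }
    mask = res.mask()
    if mask.any():
        table = decoding.extract_cluster_auc(gat_sub, mask)
        parts = table["subcondition"].str.split("|", expand=True)
        table[["drug", "accuracy", "confidence"]] = parts
        arr = np.full((len(gat_sub), len(DRUGS), 2, 2), np.nan)
        for _, r in table.iterrows():
            arr[int(r["subject"]), DRUGS.index(r["drug"]),
                ("correct", "error").index(r["accuracy"]),
                ("high", "low").index(r["confidence"])] = r["auc"]
        ok = np.isfinite(arr).all(axis=(1, 2, 3))
        if ok.sum() >= 3:
            an = rm_anova(arr[ok], {"drug": 3, "accuracy": 2, "confidence": 2})
            out["cluster_auc_rmanova"] = {
                "_x_".join(k): v.to_dict() for k, v in an.items()
            }
            err_auc = arr[ok, :, 1, :].mean(axis=(1, 2))
            out["error_trials_auc_vs_chance"] = t_test(
                err_auc, popmean=0.5).to_dict()
    return out


def _hier_section(bundle: StudyBundle, filtered: pd.DataFrame, cfg: ReportConfig,
                  seed: int) -> dict:
    counts = {d: [] for d in ("PLC", "ATX", "DNP")}
    for subj in sorted(filtered["subject"].unique()):
        for d in counts:
            sub = filtered[(filtered["subject"] == subj) & (filtered["drug"] == d)]
            counts[d].append(sdt.tabulate_counts(sub))
    mc = hierarchical.McmcConfig(
        n_samples=cfg.mcmc_samples, n_warmup=cfg.mcmc_warmup, seed=seed)
    out = {}
    for drug in ("ATX", "DNP"):
        samples = hierarchical.fit_group_paired(
            counts[drug], counts["PLC"], mc, labels=(drug, "PLC"))
        diag = hierarchical.diagnose(samples)
        s = diag["parameters"]["mu_diff"]
        out[f"{drug}_minus_PLC_logMratio"] = {
            "mean": s.mean, "sd": s.sd, "ci95": list(s.ci95),
            "p_gt_zero": s.p_gt_zero, "rhat_max": diag["rhat_max"],
        }
    return out


def run_report(
    cfg: ReportConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full synthetic-study analysis chain and return the summary."""
    cfg = cfg or ReportConfig()
    bundle = make_study(cfg.study, seed=seed)
    metrics, filtered, exclusions = _subject_metrics(bundle)

    summary: dict = {
        "seed": seed,
        "n_subjects": cfg.study.n_subjects,
        "n_trials_per_session": cfg.study.n_trials,
        "exclusions": exclusions,
        "descriptives": {
            "mean_d_prime": float(metrics["d_prime"].mean()),
            "mean_meta_d": float(metrics["meta_d"].mean()),
            "mean_m_diff": float(metrics["m_diff"].mean()),
            "mean_conf_rate": float(metrics["conf_rate"].mean()),
        },
        "stages": [],
    }
    summary["drug_effects"] = _drug_tests(metrics)
    summary["stages"].append("behavior")

    pupil_sec, _ = _pupil_section(filtered)
    summary["pupil"] = pupil_sec
    summary["stages"].append("pupil")

    if cfg.include_hierarchical:
        summary["hierarchical_m_ratio"] = _hier_section(bundle, filtered, cfg, seed)
        summary["stages"].append("hierarchical")
    if cfg.include_erp:
        summary["erp"] = _erp_section(bundle, cfg, seed)
        summary["stages"].append("erp")
    if cfg.include_decoding:
        summary["decoding"] = _decoding_section(bundle, cfg, seed)
        summary["stages"].append("decoding")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(summary, indent=2, default=_json_default))
        metrics.to_csv(out_dir / "subject_metrics.csv", index=False)
        from .io import write_manifest

        write_manifest(
            out_dir / "manifest.json", seed=seed,
            config={"n_subjects": cfg.study.n_subjects,
                    "n_trials": cfg.study.n_trials},
            stage="report", outputs=["report.json", "subject_metrics.csv"],
        )
    return summary


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)
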