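"""Figure-level analyses: learning, FA/CR, reward reversal, optogenetics.

Each ``run_*`` function orchestrates the lower-level modules over one or a
few sessions and returns ``(summary, frames)``: a JSON-serializable summary
dict and a dict of tidy DataFrames.  :func:`write_report` serializes both
deterministically (stable column order, fixed float formatting, sorted JSON
keys) so identical seeds and configs produce byte-identical reports.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from .io import SessionBundle
from .licklfp import delta_auroc_profile, lr_lfp_auroc_table
from .resampling import (
    StatResult,
    chi2_proportions,
    interaction_anova,
    permutation_anova,
    two_sample_test,
)
from .roc import auroc_table, dprime_normalize, percent_significant
from .spectral import DEFAULT_BANDS, delta_power_table

__all__ = [
    "AnalysisConfig",
    "run_learning_analysis",
    "run_facr_analysis",
    "run_reversal_analysis",
    "run_opto_analysis",
    "write_report",
]

BAND_NAMES = tuple(b.name for b in DEFAULT_BANDS)


@dataclass
class AnalysisConfig:
    """Knobs shared by the figure-level analyses.

    Epoch sizes follow the study design: 30-trial naive/proficient epochs
    for the learning and reversal analyses, 20-trial pre-laser/laser
    epochs for the optogenetic analysis.
    """

    epoch_trials: int = 30
    opto_epoch_trials: int = 20
    bands: tuple = BAND_NAMES
    q: float = 0.05
    n_perm: int = 2000
    n_boot: int = 500
    seed: int = 0
    min_fa_trials: int = 3
    contrast: str = "splus_sminus"
    include_lick_profile: bool = False
    profile_bands: tuple = ("theta", "beta")
    profile_lags: tuple = (0.0, 0.3)
    # spectrogram window step for the batched Δ power tables; any step
    # <= 0.25 s changes band Δ power by ~0.01 dB (see methods note)
    step_s: float = 0.25

    def to_dict(self) -> dict:
        return asdict(self)


def _epoch_delta_table(
    bundle: SessionBundle, sel, bands, step_s: float = 0.25
) -> pd.DataFrame:
    sub = bundle.subset(sel.trial_positions)
    df = delta_power_table(
        sub, bands=[b for b in DEFAULT_BANDS if b.name in bands], step_s=step_s
    )
    df["epoch"] = sel.label
    df["session_index"] = bundle.meta.session_index
    df["mouse_id"] = bundle.meta.mouse_id
    return df


def run_learning_analysis(
    sessions: list, config: AnalysisConfig | None = None
) -> tuple[dict, dict]:
    """Naive vs proficient odorant-value discrimination (per band).

    Per band: per-electrode S+/S− auROC in the naive and proficient epochs,
    a permutation ANOVA on the two auROC distributions, and FDR-corrected
    percent-significant summaries compared by chi-squared.
    """
    config = config or AnalysisConfig()
    ss = np.random.SeedSequence(config.seed)
    seeds = iter(int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(64))

    frames_aurocs = []
    psig_frames = []
    for label in ("naive", "proficient"):
        sel = beh.select_epoch(sessions, label, config.epoch_trials)
        delta = _epoch_delta_table(sessions[sel.session_pos], sel, config.bands, config.step_s)
        aur = auroc_table(delta, contrast=config.contrast)
        aur["epoch"] = label
        frames_aurocs.append(aur)
        psig = percent_significant(aur, q=config.q)
        psig["epoch"] = label
        psig_frames.append(psig)
    aurocs = pd.concat(frames_aurocs, ignore_index=True)
    psig = pd.concat(psig_frames, ignore_index=True)

    band_rows = []
    for band in config.bands:
        a_nv = aurocs.query("band == @band and epoch == 'naive'")["auroc"].to_numpy()
        a_pf = aurocs.query("band == @band and epoch == 'proficient'")["auroc"].to_numpy()
        if min(a_nv.size, a_pf.size) < 2:
            import warnings

            warnings.warn(
                f"band {band}: fewer than 2 electrodes per epoch; "
                "permutation ANOVA skipped (n=1 family)"
            )
            res = StatResult("perm_anova", np.nan, np.nan, 0, None, (a_nv.size, a_pf.size))
        else:
            res = permutation_anova([a_nv, a_pf], n_perm=config.n_perm, seed=next(seeds))
        row_nv = psig.query("band == @band and epoch == 'naive'").iloc[0]
        row_pf = psig.query("band == @band and epoch == 'proficient'").iloc[0]
        chi = chi2_proportions(
            int(row_nv["n_significant"]), int(row_nv["n_total"]),
            int(row_pf["n_significant"]), int(row_pf["n_total"]),
        )
        band_rows.append(
            {
                "band": band,
                "auroc_naive_mean": float(a_nv.mean()),
                "auroc_proficient_mean": float(a_pf.mean()),
                "perm_anova_F": res.statistic,
                "perm_anova_p": res.p_value,
                "chi2": chi.statistic,
                "chi2_p": chi.p_value,
                "n_electrodes": int(a_nv.size),
            }
        )
    band_tests = pd.DataFrame(band_rows)
    summary = {
        "analysis": "learning",
        "config": config.to_dict(),
        "bands": {
            r["band"]: {
                "auroc_naive_mean": r["auroc_naive_mean"],
                "auroc_proficient_mean": r["auroc_proficient_mean"],
                "perm_anova_p": r["perm_anova_p"],
                "chi2_p": r["chi2_p"],
            }
            for r in band_rows
        },
    }
    return summary, {"aurocs": aurocs, "percent_significant": psig, "band_tests": band_tests}


def run_facr_analysis(
    sessions: list, config: AnalysisConfig | None = None
) -> tuple[dict, dict]:
    """Hit / CR / FA d′ distributions and FA/CR vs Hit/CR auROC (proficient)."""
    config = config or AnalysisConfig()
    sel = beh.select_epoch(sessions, "proficient", config.epoch_trials)
    bundle = sessions[sel.session_pos]
    delta = _epoch_delta_table(bundle, sel, config.bands, config.step_s)
    n_fa = int((delta["outcome"] == "FA").sum() // max(len(config.bands), 1)
               // max(bundle.lfp.n_electrodes, 1))
    skipped = n_fa < config.min_fa_trials

    dprime_rows = []
    auroc_frames = []
    for band in config.bands:
        sub = delta.query("band == @band").dropna(subset=["delta_db"])
        by_class = {
            c: sub.loc[sub["outcome"] == c, "delta_db"].to_numpy()
            for c in ("Hit", "CR", "FA")
            if (sub["outcome"] == c).sum() >= 2
        }
        if {"Hit", "CR"} <= set(by_class):
            dp = dprime_normalize(by_class)
            for cls, vals in dp.items():
                for v in vals:
                    dprime_rows.append({"band": band, "outcome": cls, "dprime": float(v)})
        for contrast in ("hit_cr",) + (() if skipped else ("fa_cr",)):
            aur = auroc_table(sub, contrast=contrast)
            if len(aur):
                aur["band"] = band
                auroc_frames.append(aur)
    aurocs = (
        pd.concat(auroc_frames, ignore_index=True) if auroc_frames else pd.DataFrame()
    )
    summary = {
        "analysis": "facr",
        "config": config.to_dict(),
        "n_fa_trials": n_fa,
        "fa_analysis_skipped": bool(skipped),
        "bands": {},
    }
    for band in config.bands:
        entry = {}
        for contrast in ("hit_cr", "fa_cr"):
            sel_rows = aurocs.query("band == @band and contrast == @contrast") if len(aurocs) else pd.DataFrame()
            if len(sel_rows):
                entry[f"auroc_{contrast}_mean"] = float(sel_rows["auroc"].mean())
        summary["bands"][band] = entry
    return summary, {"aurocs": aurocs, "dprime": pd.DataFrame(dprime_rows)}


def run_reversal_analysis(
    forward: SessionBundle,
    reversed_: SessionBundle,
    config: AnalysisConfig | None = None,
) -> tuple[dict, dict]:
    """Polarity of the odorant-evoked Δ power contrast across reward reversal.

    The per-session contrast is mean Δ power on odorant A minus odorant B
    (identity, not valence).  A *flip* is declared for a band when the
    contrast is individually significant in both sessions (rank-sum,
    p < 0.01) with opposite signs — the signature of value-locked (rather
    than identity-locked) oscillatory changes.
    """
    config = config or AnalysisConfig()
    if forward.meta.reward_mapping == reversed_.meta.reward_mapping:
        raise ValueError("forward and reversed sessions share the same reward mapping")
    ss = np.random.SeedSequence(config.seed)
    seeds = iter(int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(64))

    tables = {}
    for name, bundle in (("forward", forward), ("reversed", reversed_)):
        sel = beh.select_epoch([bundle], "proficient", config.epoch_trials)
        df = _epoch_delta_table(bundle, sel, config.bands, config.step_s)
        # odorant identity from valence + reward mapping
        mapping = bundle.meta.reward_mapping
        df["odorant"] = np.where(
            df["valence"] == "Splus", mapping, "B" if mapping == "A" else "A"
        )
        df["session"] = name
        tables[name] = df
    both = pd.concat(tables.values(), ignore_index=True)

    band_rows = []
    for band in config.bands:
        row = {"band": band}
        signs = {}
        for name in ("forward", "reversed"):
            sub = tables[name].query("band == @band").dropna(subset=["delta_db"])
            a = sub.loc[sub["odorant"] == "A", "delta_db"].to_numpy()
            b = sub.loc[sub["odorant"] == "B", "delta_db"].to_numpy()
            contrast = float(a.mean() - b.mean())
            test = two_sample_test(a, b, method="ranksum")
            row[f"contrast_{name}_db"] = contrast
            row[f"contrast_{name}_p"] = test.p_value
            signs[name] = np.sign(contrast) if test.p_value < 0.01 else 0.0
        for odorant in ("A", "B"):
            f_vals = tables["forward"].query(
                "band == @band and odorant == @odorant"
            )["delta_db"].dropna().to_numpy()
            r_vals = tables["reversed"].query(
                "band == @band and odorant == @odorant"
            )["delta_db"].dropna().to_numpy()
            res = permutation_anova(
                [f_vals, r_vals], n_perm=config.n_perm, seed=next(seeds)
            )
            row[f"perm_p_odorant_{odorant}"] = res.p_value
        row["flip"] = bool(signs["forward"] * signs["reversed"] < 0)
        band_rows.append(row)
    band_tests = pd.DataFrame(band_rows)
    summary = {
        "analysis": "reversal",
        "config": config.to_dict(),
        "n_bands_flipped": int(band_tests["flip"].sum()),
        "bands": {
            r["band"]: {
                "flip": r["flip"],
                "contrast_forward_db": r["contrast_forward_db"],
                "contrast_reversed_db": r["contrast_reversed_db"],
            }
            for r in band_rows
        },
    }
    return summary, {"delta_power": both, "band_tests": band_tests}


def _epoch_percent_correct(bundle: SessionBundle, sel) -> float:
    tab = beh.outcome_table(bundle.subset(sel.trial_positions))
    return float(100.0 * tab["correct"].mean())


def run_opto_analysis(
    sessions_by_genotype: dict,
    config: AnalysisConfig | None = None,
) -> tuple[dict, dict]:
    """Genotype x laser factorial analysis of Δ power auROC.

    ``sessions_by_genotype`` maps ``"control"`` / ``"opsin"`` to the
    per-mouse ordered session lists of that genotype (one list per mouse,
    laser-off sessions before laser-on; a single flat list of bundles is
    accepted for one mouse).  Electrodes are pooled across mice within a
    genotype, as (mouse x electrode) units.  Produces: per-band
    per-contrast per-unit auROCs in the four cells with the genotype x
    laser interaction ANOVA; the Δ-power-based ΔauROC with bootstrap CI;
    the behavioral pre-vs-laser comparison per genotype (paired over mice
    when possible); and optionally the lick-locked (LR-LFP) ΔauROC profile
    over a band x lag grid.
    """
    config = config or AnalysisConfig()
    for g in ("control", "opsin"):
        if g not in sessions_by_genotype:
            raise ValueError(f"missing genotype {g!r}")
    ss = np.random.SeedSequence(config.seed)
    seeds = iter(int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(256))

    cells = {}  # (genotype, epoch) -> list of (bundle, epoch selection)
    behavior_rows = []
    for g, mice in sessions_by_genotype.items():
        if mice and isinstance(mice[0], SessionBundle):
            mice = [mice]
        for mouse_sessions in mice:
            for epoch, label in (("pre", "pre_laser"), ("laser", "laser")):
                sel = beh.select_epoch(mouse_sessions, label, config.opto_epoch_trials)
                bundle = mouse_sessions[sel.session_pos]
                cells.setdefault((g, epoch), []).append((bundle, sel))
                behavior_rows.append(
                    {
                        "genotype": g,
                        "epoch": epoch,
                        "mouse_id": bundle.meta.mouse_id,
                        "percent_correct": _epoch_percent_correct(bundle, sel),
                    }
                )
    behavior_df = pd.DataFrame(behavior_rows)

    delta_by_cell = {
        key: pd.concat(
            [_epoch_delta_table(b, sel, config.bands, config.step_s) for b, sel in members],
            ignore_index=True,
        )
        for key, members in cells.items()
    }
    auroc_frames = {}
    for contrast in ("splus_sminus", "hit_cr"):
        per_cell = {}
        for (g, epoch), delta in delta_by_cell.items():
            aur = auroc_table(
                delta, contrast=contrast, group_cols=("mouse_id", "electrode", "band")
            )
            aur["genotype"] = g
            aur["epoch"] = epoch
            per_cell[(g, epoch)] = aur
        auroc_frames[contrast] = per_cell

    interaction_rows = []
    for contrast, per_cell in auroc_frames.items():
        allc = pd.concat(per_cell.values(), ignore_index=True)
        for band in config.bands:
            sub = allc.query("band == @band")
            if sub.groupby(["genotype", "epoch"]).size().shape[0] < 4:
                continue
            res = interaction_anova(
                sub["auroc"].to_numpy(), sub["genotype"].to_numpy(), sub["epoch"].to_numpy()
            )
            interaction_rows.append(
                {
                    "contrast": contrast,
                    "band": band,
                    "interaction_F": res.statistic,
                    "interaction_p": res.p_value,
                }
            )
    interactions = pd.DataFrame(interaction_rows)

    # Δ-power-based ΔauROC per band (S+/S− contrast), bootstrap over electrodes
    profile_cells = {
        key: df.rename(columns={})
        for key, df in auroc_frames[config.contrast].items()
    }
    delta_auroc = delta_auroc_profile(
        profile_cells,
        n_boot=config.n_boot,
        seed=next(seeds),
        q=config.q,
        grid_cols=("band",),
    )

    # behavioral paired comparison pre vs laser per genotype
    behavior_tests = {}
    for g in ("control", "opsin"):
        pre = behavior_df.query("genotype == @g and epoch == 'pre'")["percent_correct"]
        las = behavior_df.query("genotype == @g and epoch == 'laser'")["percent_correct"]
        entry = {
            "percent_correct_pre": float(pre.mean()),
            "percent_correct_laser": float(las.mean()),
        }
        if len(pre) >= 2 and len(pre) == len(las):
            t = two_sample_test(pre.to_numpy(), las.to_numpy(), method="paired_t")
            entry["paired_t_p"] = t.p_value
        behavior_tests[g] = entry

    frames = {
        "aurocs": pd.concat(
            [df for per_cell in auroc_frames.values() for df in per_cell.values()],
            ignore_index=True,
        ),
        "interactions": interactions,
        "delta_auroc": delta_auroc,
        "behavior": behavior_df,
    }

    if config.include_lick_profile:
        lick_cells = {}
        for (g, epoch), members in cells.items():
            tabs = []
            for bundle, sel in members:
                tab = lr_lfp_auroc_table(
                    bundle.subset(sel.trial_positions),
                    bands=config.profile_bands,
                    lags=config.profile_lags,
                    contrast="hit_cr",
                    seed=next(seeds),
                )
                tab["mouse_id"] = bundle.meta.mouse_id
                tabs.append(tab)
            lick_cells[(g, epoch)] = pd.concat(tabs, ignore_index=True)
        frames["lick_delta_auroc"] = delta_auroc_profile(
            lick_cells,
            n_boot=config.n_boot,
            seed=next(seeds),
            q=config.q,
            grid_cols=("band", "lag_s"),
        )

    summary = {
        "analysis": "opto",
        "config": config.to_dict(),
        "interaction_p": {
            f"{r['contrast']}:{r['band']}": r["interaction_p"] for r in interaction_rows
        },
        "delta_auroc": {
            r["band"]: {
                "delta_auroc": r["delta_auroc"],
                "ci_lo": r["ci_lo"],
                "ci_hi": r["ci_hi"],
                "p_interaction": r["p_interaction"],
            }
            for _, r in delta_auroc.iterrows()
        },
        "behavior": behavior_tests,
    }
    return summary, frames


def write_report(out_dir, summary: dict, frames: dict) -> Path:
    """Serialize a report deterministically: summary.json + one CSV per frame."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
    for name, df in frames.items():
        df.to_csv(out_dir / f"{name}.csv", index=False, float_format="%.10g")
    return out_dir


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
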