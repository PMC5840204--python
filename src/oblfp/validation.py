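"""End-to-end validation benchmarks on synthetic sessions.

Each function generates its own inputs from a seed, runs the relevant part
of the pipeline, and returns the measured quantity together with the
problem size — parameter-recovery checks (programmed dB steps, auROC
against its closed-form expectation, lick-phase concentration), statistical
calibration checks (null percent-significant under FDR, permutation-test
type-I error), the figure-level analyses on generators with programmed
effects, and byte-level determinism of the command-line verbs.

These are the quantitative claims the package makes about itself; the test
suite asserts them and ``scripts/acceptance.py`` reports them.
"""

from __future__ import annotations

import filecmp
import warnings
from pathlib import Path

import numpy as np
from scipy import stats as sstats
from scipy.special import iv as _bessel_iv

from . import pipeline as pl
from . import simulate as sim
from .licklfp import lick_theta_phase
from .resampling import permutation_anova
from .roc import auroc_centered, auroc_table, fdr_correct, percent_significant
from .simulate import ThetaPhase, _unit_band_noise, simulate_lick_train
from .spectral import BAND_BY_NAME, delta_power, delta_power_table, spectrogram

FS = 1000.0


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(c.generate_state(1)[0] % (2**31)) for c in np.random.SeedSequence(seed).spawn(n)]


# ----------------------------------------------------------------------
# Δ power exactness


def delta_power_step_recovery(seed: int, n_repeats: int = 200) -> dict:
    """Recover a programmed amplitude doubling (expected +6.02 dB) and a null.

    A pure beta-band noise process doubles its amplitude (with a 100 ms
    cosine ramp) during each of ``n_repeats`` odorant-like windows; Δ power
    is measured per window and averaged.  The stationary control runs the
    same measurement without the amplitude step.
    """
    rng = np.random.default_rng(seed)
    band = BAND_BY_NAME["beta"]
    period = 7.0
    dur = n_repeats * period + 4.0
    n = int(dur * FS)
    x = _unit_band_noise(rng, n, FS, band)
    onsets = 4.0 + period * np.arange(n_repeats) + 1.2
    env = np.ones((1, n), dtype=np.float32)
    for on in onsets:
        sim._apply_envelope(
            env, int(on * FS), int((on + 2.5) * FS), 2.0, int(0.1 * FS)
        )
    stepped = x * env[0]
    spec_step = spectrogram(stepped, FS)
    spec_null = spectrogram(x, FS)
    d_step = np.mean([delta_power(spec_step, on, band) for on in onsets])
    d_null = np.mean([delta_power(spec_null, on, band) for on in onsets])
    return {
        "doubling_db": float(d_step),
        "null_abs_db": float(abs(d_null)),
        "n": n_repeats,
    }


# ----------------------------------------------------------------------
# auROC against exhaustive pair counting


def _pair_counting_auroc(pos: np.ndarray, neg: np.ndarray) -> float:
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    n = pos.size * neg.size
    return (wins + 0.5 * ties - n / 2.0) / n


def auroc_matches_pair_counting(seed: int, n_sets: int = 200) -> dict:
    """Rank-based centered auROC vs brute-force ordered-pair counting.

    Small integer score sets guarantee ties; agreement must be exact.
    """
    rng = np.random.default_rng(seed)
    n_exact = 0
    max_err = 0.0
    for _ in range(n_sets):
        n_pos = int(rng.integers(2, 13))
        n_neg = int(rng.integers(2, 13))
        pos = rng.integers(0, 6, size=n_pos).astype(float)
        neg = rng.integers(0, 6, size=n_neg).astype(float)
        a = auroc_centered(pos, neg).auroc
        b = _pair_counting_auroc(pos, neg)
        err = abs(a - b)
        max_err = max(max_err, err)
        n_exact += err < 1e-12
    return {"fraction_exact": n_exact / n_sets, "max_abs_error": max_err, "n": n_sets}


# ----------------------------------------------------------------------
# auROC recovery at a programmed effect size


def auroc_recovery(seed: int, n_seeds: int = 20) -> dict:
    """Mean beta-band S+/S− auROC at a 6 dB contrast with 3 dB trial SD.

    With per-trial Δ power ~ N(6, 3²) on S+ and N(0, 3²) on S−, the
    population centered auROC is Φ(6 / (3·√2)) − 0.5 ≈ 0.421; sessions of
    30 S+ and 30 S− trials are generated and analyzed end to end.
    """
    vals = []
    for s in _child_seeds(seed, n_seeds):
        cfg = sim.SimConfig(seed=s, n_trials=60, n_electrodes=4, effect_sd_db=3.0)
        cfg.band_effects["beta"].delta_db_splus = 6.0
        bundle, _ = sim.simulate_session(cfg)
        table = delta_power_table(bundle, step_s=0.25)
        aur = auroc_table(table.query("band == 'beta'"), group_cols=("electrode",))
        vals.append(aur["auroc"].mean())
    expected = float(sstats.norm.cdf(6.0 / (3.0 * np.sqrt(2.0))) - 0.5)
    return {
        "mean_auroc": float(np.mean(vals)),
        "expected_auroc": expected,
        "n": n_seeds,
    }


# ----------------------------------------------------------------------
# Null calibration of percent-significant auROCs


def null_percent_significant(seed: int, n_seeds: int = 10) -> dict:
    """FDR-controlled percent of significant auROCs with no programmed effect.

    96 electrodes per seed, all band effects zero; families are all
    electrodes of one band.
    """
    percents = []
    for s in _child_seeds(seed, n_seeds):
        cfg = sim.SimConfig(seed=s, n_trials=40, n_electrodes=96)
        bundle, _ = sim.simulate_session(cfg)
        table = delta_power_table(bundle, step_s=0.25)
        aur = auroc_table(table)
        psig = percent_significant(aur, q=0.05)
        percents.append(psig["percent_significant"].mean())
    return {
        "mean_percent_significant": float(np.mean(percents)),
        "n": n_seeds,
        "n_electrodes": 96,
    }


# ----------------------------------------------------------------------
# Permutation ANOVA validity


def perm_anova_exhaustive() -> dict:
    """Exact p for two disjoint 5-value groups: 2 of 252 assignments."""
    res = permutation_anova(
        [[1.0, 2.0, 3.0, 4.0, 5.0], [10.0, 11.0, 12.0, 13.0, 14.0]],
        exhaustive=True,
    )
    return {"p_value": res.p_value, "expected": 2.0 / 252.0, "n": res.n_perm}


def perm_anova_type1(seed: int, n_sims: int = 1000, n_perm: int = 500) -> dict:
    """Empirical type-I error of the permutation ANOVA at alpha = 0.05."""
    rng = np.random.default_rng(seed)
    seeds = _child_seeds(seed + 1, n_sims)
    rejections = 0
    for s in seeds:
        a = rng.standard_normal(10)
        b = rng.standard_normal(10)
        res = permutation_anova([a, b], n_perm=n_perm, seed=s)
        rejections += res.p_value <= 0.05
    return {"rejection_rate": rejections / n_sims, "alpha": 0.05, "n": n_sims}


# ----------------------------------------------------------------------
# Figure-level analyses on programmed generators


def learning_analysis_power(seed: int, n_seeds: int = 10) -> dict:
    """Fraction of seeds where proficiency raises the auROC in every band.

    Generator: 6 dB S+/S− contrast ramping 0→full across the first session,
    sustained in the second; success = proficient mean auROC above naive
    and permutation-ANOVA p < 0.01 in all four bands.
    """
    successes = 0
    for s in _child_seeds(seed, n_seeds):
        cfgs = sim.learning_session_configs(s)
        sessions = [sim.simulate_session(c)[0] for c in cfgs]
        summary, _ = pl.run_learning_analysis(sessions, pl.AnalysisConfig(seed=s))
        ok = all(
            (b["auroc_proficient_mean"] > b["auroc_naive_mean"])
            and (b["perm_anova_p"] < 0.01)
            for b in summary["bands"].values()
        )
        successes += ok
    return {"fraction_significant": successes / n_seeds, "n": n_seeds}


def reversal_polarity(seed: int) -> dict:
    """Band count with a detected Δ power polarity flip across reward reversal.

    Value-locked effects must flip in all four bands; identity-locked
    effects (tied to the chemical, the discriminating control) must not
    flip anywhere.
    """
    out = {}
    for label, locked in (("value_locked", True), ("identity_locked", False)):
        cfg_f, cfg_r = sim.reversal_session_configs(seed, value_locked=locked)
        fwd, _ = sim.simulate_session(cfg_f)
        rev, _ = sim.simulate_session(cfg_r)
        summary, _ = pl.run_reversal_analysis(fwd, rev, pl.AnalysisConfig(seed=seed))
        out[f"{label}_flips"] = summary["n_bands_flipped"]
    out["n_bands"] = 4
    return out


def opto_interaction_effects(seed: int, n_seeds: int = 10, n_inert: int = 5) -> dict:
    """Genotype x laser interaction with opsin laser contrast silenced vs inert.

    Silenced (opsin laser factor 0): every band's S+/S− interaction should
    survive FDR, and the Δ-power ΔauROC should sit near −(pre-epoch auROC)
    inside its bootstrap CI.  Inert laser: significant interactions should
    stay at the FDR-expected level.
    """
    def run(s, factor):
        cfgs = sim.opto_cell_configs(s, laser_effect_opsin=factor)
        by_g = {
            g: [[sim.simulate_session(c)[0] for c in pair] for pair in cfgs[g]]
            for g in ("control", "opsin")
        }
        return pl.run_opto_analysis(by_g, pl.AnalysisConfig(seed=s))

    n_success = 0
    covered = 0
    discrepancies = []
    n_cells = 0
    for s in _child_seeds(seed, n_seeds):
        summary, frames = run(s, 0.0)
        ps = np.array(
            [v for k, v in summary["interaction_p"].items() if k.startswith("splus")]
        )
        n_success += bool(fdr_correct(ps, q=0.05).significant.all())
        aur = frames["aurocs"]
        pre = (
            aur.query("contrast == 'splus_sminus' and epoch == 'pre'")
            .groupby("band")["auroc"]
            .mean()
        )
        for band, d in summary["delta_auroc"].items():
            target = -float(pre[band])
            covered += d["ci_lo"] <= target <= d["ci_hi"]
            discrepancies.append(d["delta_auroc"] - target)
            n_cells += 1

    inert_sig = 0
    inert_cells = 0
    for s in _child_seeds(seed + 1, n_inert):
        summary, _ = run(s, 1.0)
        ps = np.array(
            [v for k, v in summary["interaction_p"].items() if k.startswith("splus")]
        )
        inert_sig += int(fdr_correct(ps, q=0.05).significant.sum())
        inert_cells += ps.size
    return {
        "interaction_fraction": n_success / n_seeds,
        "ci_coverage": covered / n_cells,
        "mean_discrepancy": float(np.mean(discrepancies)),
        "inert_significant_fraction": inert_sig / inert_cells,
        "n": n_seeds,
        "n_inert": n_inert,
    }


# ----------------------------------------------------------------------
# Lick-phase recovery


def lick_phase_recovery(seed: int, duration_s: float = 160.0) -> dict:
    """Resultant length of lick theta phases at kappa = 2 and kappa = 0.

    ~1000 licks are placed on a synthetic theta process and their phases
    re-measured through the analysis path (zero-phase filter + Hilbert).
    The kappa = 2 expectation is I1(2)/I0(2) ≈ 0.698.
    """
    rng = np.random.default_rng(seed)
    band = BAND_BY_NAME["theta"]
    n = int(duration_s * FS)
    theta = _unit_band_noise(rng, n, FS, band)
    from scipy.signal import hilbert

    phase = ThetaPhase(
        np.arange(n) / FS, np.unwrap(np.angle(hilbert(theta.astype(float))))
    )
    out = {}
    for kappa, label in ((2.0, "kappa2"), (0.0, "uniform")):
        times, _ = simulate_lick_train(
            (2.0, duration_s - 2.0), 7.0, phase, kappa, np.random.default_rng(seed + 1)
        )
        res = lick_theta_phase(theta, FS, times)
        out[f"resultant_{label}"] = res.resultant_length
        out[f"n_{label}"] = res.n
    out["expected_kappa2"] = float(_bessel_iv(1, 2.0) / _bessel_iv(0, 2.0))
    return out


# ----------------------------------------------------------------------
# Determinism of the CLI verbs


def cli_determinism(seed: int, workdir) -> dict:
    """Run every pipeline verb twice with one seed; outputs must be identical."""
    from click.testing import CliRunner
    from .cli import main as cli_main

    workdir = Path(workdir)
    runner = CliRunner()

    def invoke(args):
        res = runner.invoke(cli_main, [str(a) for a in args], catch_exceptions=False)
        if res.exit_code != 0:
            raise RuntimeError(f"CLI failed: {args}: {res.output}")

    cfg_yaml = workdir / "sim.yaml"

    def run_all(root: Path):
        root.mkdir(parents=True, exist_ok=True)
        sess = root / "session"
        invoke(["simulate", "--config", cfg_yaml, "--out", sess, "--seed", seed])
        invoke(["behavior", "--session", sess, "--out", root / "outcomes.csv"])
        invoke(["spectral", "--session", sess, "--out", root / "delta.csv"])
        invoke(["roc", "--delta", root / "delta.csv", "--out", root / "roc.csv"])
        invoke(
            ["stats", "--in", root / "delta.csv", "--test", "perm_anova",
             "--value-col", "delta_db", "--group-col", "valence",
             "--n-perm", 200, "--seed", seed, "--out", root / "stats.json"]
        )
        invoke(
            ["lickerp", "--session", sess, "--band", "theta", "--lag", 0.3,
             "--seed", seed, "--out", root / "lr_roc.csv"]
        )
        invoke(
            ["run", "learning", "--trials", 40, "--electrodes", 4,
             "--seed", seed, "--out", root / "learning"]
        )
        invoke(
            ["run", "reversal", "--trials", 40, "--electrodes", 4,
             "--seed", seed, "--out", root / "reversal"]
        )
        invoke(
            ["run", "opto", "--mice", 1, "--trials", 30, "--electrodes", 4,
             "--seed", seed, "--out", root / "opto"]
        )

    workdir.mkdir(parents=True, exist_ok=True)
    cfg_yaml.write_text("n_trials: 30\nn_electrodes: 2\n")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        run_all(workdir / "a")
        run_all(workdir / "b")

    a_files = sorted(
        p.relative_to(workdir / "a") for p in (workdir / "a").rglob("*") if p.is_file()
    )
    b_files = sorted(
        p.relative_to(workdir / "b") for p in (workdir / "b").rglob("*") if p.is_file()
    )
    identical = a_files == b_files and all(
        filecmp.cmp(workdir / "a" / f, workdir / "b" / f, shallow=False)
        for f in a_files
    )
    return {"identical": float(identical), "n_files": len(a_files)}
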