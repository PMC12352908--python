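"""Validation studies: quantitative self-checks of the whole pipeline.

Each function runs a simulation study against the synthetic-data
generators' ground truth and returns a dictionary of scalar metrics.
The test suite asserts on these metrics; ``scripts/acceptance.py``
reports them. Problem sizes are chosen so the full battery runs in a
few minutes on one CPU (documented in the methods note).
"""

from __future__ import annotations

import itertools
import math
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .amplicon import example_design
from .classify import (
    AMBIGUOUS,
    INDEL,
    MUT_KI,
    UNEDITED,
    WTSTAR_KI,
    ReadClassifier,
    quantify_sample,
)
from .cohort import compute_tmb, fit_signatures_nnls, harmonize_tmb
from .cooccur import (
    build_alteration_matrix,
    discover_pair_test,
    discover_screen,
    fisher_pair_test,
    fit_background,
)
from .select_stats import analyze_select
from .stats import fisher_exact_2x2, poisson_binomial_cdf, wilcoxon_rank_sum
from .survival import cox_ph_fit, km_curve, logrank_test
from .synthetic import (
    simulate_cohort,
    simulate_select_counts,
    simulate_select_experiment,
    standard_select_mix,
)
from .synthetic.cohort import make_synthetic_signatures
from .synthetic.select import _mutate_reads, allele_sequence


# -- classifier vs planted truth ------------------------------------------


def classifier_truth_study(seed: int = 1, depth: int = 5000,
                           error_rate: float = 0.005) -> dict:
    """Per-read accuracy and Mut:WT* ratio bias against simulator truth.

    Error-free deterministic reads must be classified perfectly; under
    per-base substitution errors the per-read category accuracy and the
    relative bias of the classified Mut:WT* ratio are measured.
    """
    design = example_design()
    mix = standard_select_mix(design, mut_cisplatin_fitness=0.8)

    # error-free, deterministic: classification must recover the planted
    # allele fractions exactly
    with tempfile.TemporaryDirectory() as td:
        paths, truth = simulate_select_experiment(
            design, mix, td, depth=1000, error_rate=0.0, replicates=1,
            seed=seed, deterministic=True,
        )
        n_exact = n_total = 0
        for (day, cond, rep), path in paths.items():
            table = quantify_sample(path, design, day, cond, rep)
            fractions = truth.allele_fractions[(day, cond)]
            for cat in (MUT_KI, WTSTAR_KI, UNEDITED, INDEL):
                planted = round(
                    1000 * sum(f for (k, _), f in fractions.items() if k == cat)
                )
                n_exact += min(table.counts[cat], planted)
                n_total += planted
    accuracy_errorfree = 100.0 * n_exact / n_total

    # noisy reads with per-read labels
    rng = np.random.default_rng(seed)
    clf = ReadClassifier(design)
    truth0 = {}
    for g, f in mix.items():
        for a in (g.allele1, g.allele2):
            key = (a.kind, a.indel)
            truth0[key] = truth0.get(key, 0.0) + 0.5 * f
    correct = total = 0
    mut_counts, wts_counts = [], []
    from .synthetic.select import Allele

    for _rep in range(6):
        rep_counts = {MUT_KI: 0, WTSTAR_KI: 0}
        for (kind, indel), frac in sorted(truth0.items()):
            n = int(round(frac * depth))
            seq = allele_sequence(design, Allele(kind, indel))
            for read in _mutate_reads(seq, n, error_rate, rng):
                called = clf.classify(read).category
                correct += called == kind
                total += 1
                if called in rep_counts:
                    rep_counts[called] += 1
        mut_counts.append(rep_counts[MUT_KI])
        wts_counts.append(rep_counts[WTSTAR_KI])
    accuracy_noisy = 100.0 * correct / total
    planted_ratio = truth0[(MUT_KI, None)] / truth0[(WTSTAR_KI, None)]
    measured_ratio = np.mean(np.array(mut_counts) / np.array(wts_counts))
    ratio_bias_pct = 100.0 * abs(measured_ratio / planted_ratio - 1.0)
    return {
        "accuracy_errorfree_pct": accuracy_errorfree,
        "accuracy_noisy_pct": accuracy_noisy,
        "ratio_bias_pct": float(ratio_bias_pct),
        "n_reads_noisy": total,
    }


# -- selection-statistic recovery -----------------------------------------


def selection_recovery_study(seed: int = 1, depth: int = 10_000,
                             error_rate: float = 0.005,
                             w_grid=(1.0, 0.9, 0.8, 0.6)) -> dict:
    """Mean normalized R(D12, treated) vs the closed form w^10.

    The standard experiment (3 replicates) is simulated to FASTQ,
    classified, and analyzed end to end for each planted daily cisplatin
    fitness w. The z-score uses the delta-method standard error of the
    mean R propagated from the four knock-in counts of each replicate
    (the empirical SD over 3 replicates has only 2 degrees of freedom).
    """
    design = example_design()
    out = {"w": list(w_grid), "mean_R": [], "truth_R": [], "z": []}
    for iw, w in enumerate(w_grid):
        mix = standard_select_mix(design, mut_cisplatin_fitness=w)
        with tempfile.TemporaryDirectory() as td:
            paths, truth = simulate_select_experiment(
                design, mix, td, depth=depth, error_rate=error_rate,
                replicates=3, seed=seed * 1000 + iw,
            )
            tables = [
                quantify_sample(p, design, day, cond, rep)
                for (day, cond, rep), p in paths.items()
            ]
        res = analyze_select(tables)
        Rs = np.array(res.replicate_R(12, "treated"))
        by = {(t.timepoint, t.condition, t.replicate): t for t in tables}
        variances = []
        for rep in (1, 2, 3):
            Ri = res.normalized[(12, "treated", rep)]
            inv = sum(
                1.0 / by[(d, "treated", rep)].counts[c]
                for d in (2, 12)
                for c in (MUT_KI, WTSTAR_KI)
            )
            variances.append(Ri**2 * inv)
        se = math.sqrt(sum(variances)) / 3
        mean_R = float(Rs.mean())
        truth_R = truth.expected_R[(12, "treated")]
        out["mean_R"].append(mean_R)
        out["truth_R"].append(float(truth_R))
        out["z"].append((mean_R - truth_R) / se)
    out["max_abs_z"] = float(np.max(np.abs(out["z"])))
    out["monotone_decreasing"] = bool(
        np.all(np.diff(out["mean_R"]) < 0)
        if np.all(np.diff(out["w"]) < 0)
        else np.all(np.diff(out["mean_R"]) > 0)
    )
    return out


# -- neutral type-I error --------------------------------------------------


def neutral_type_i_study(seed: int = 1, n_runs: int = 1000,
                         depth: int = 5000, alpha: float = 0.05) -> dict:
    """Rejection rate of the paired endpoint t-test under neutrality."""
    design = example_design()
    mix = standard_select_mix(design, mut_cisplatin_fitness=1.0)
    rejections = 0
    for i in range(n_runs):
        tables, _ = simulate_select_counts(
            mix, depth=depth, replicates=3, seed=seed * 100_000 + i
        )
        res = analyze_select(tables)
        rejections += res.tests["treated_vs_untreated"].p < alpha
    return {"rejection_rate": rejections / n_runs, "n_runs": n_runs}


# -- exact-test enumeration oracles ---------------------------------------


def exact_test_oracle_study(seed: int = 1, n_instances: int = 40) -> dict:
    """Max |difference| between exact tests and brute-force enumeration."""
    rng = np.random.default_rng(seed)

    worst_fisher = 0.0
    for _ in range(n_instances):
        t = rng.integers(0, 7, size=4)
        a, b, c, d = (int(v) for v in t)
        r1, r2, c1 = a + b, c + d, a + c
        if r1 == 0 or r2 == 0 or c1 == 0 or b + d == 0:
            continue
        total = math.comb(r1 + r2, c1)
        probs = {
            x: math.comb(r1, x) * math.comb(r2, c1 - x) / total
            for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        }
        p_oracle = sum(p for p in probs.values() if p <= probs[a] * (1 + 1e-9))
        p_mine = fisher_exact_2x2([[a, b], [c, d]]).p
        worst_fisher = max(worst_fisher, abs(p_mine - p_oracle))

    worst_wilcoxon = 0.0
    for _ in range(n_instances):
        nx, ny = int(rng.integers(2, 5)), int(rng.integers(2, 5))
        vals = rng.permutation(30)[: nx + ny]
        x, y = list(vals[:nx]), list(vals[nx:])
        pooled = sorted(x + y)
        ranks = {v: i + 1 for i, v in enumerate(pooled)}
        w_obs = sum(ranks[v] for v in x)
        sums = [sum(cb) for cb in itertools.combinations(range(1, nx + ny + 1), nx)]
        lower = sum(s <= w_obs for s in sums) / len(sums)
        upper = sum(s >= w_obs for s in sums) / len(sums)
        p_oracle = min(1.0, 2 * min(lower, upper))
        worst_wilcoxon = max(worst_wilcoxon, abs(wilcoxon_rank_sum(x, y).p - p_oracle))

    worst_pb = 0.0
    for _ in range(8):
        n = int(rng.integers(4, 13))
        probs = rng.random(n)
        k = int(rng.integers(0, n + 1))
        lower, upper = poisson_binomial_cdf(list(probs), k)
        plo = pup = 0.0
        for bits in itertools.product([0, 1], repeat=n):
            pr = math.prod(p if b else 1 - p for p, b in zip(probs, bits))
            s = sum(bits)
            plo += pr * (s <= k)
            pup += pr * (s >= k)
        worst_pb = max(worst_pb, abs(lower - plo), abs(upper - pup))

    return {
        "fisher_max_abs_diff": worst_fisher,
        "wilcoxon_max_abs_diff": worst_wilcoxon,
        "poisson_binomial_max_abs_diff": worst_pb,
    }


# -- DISCOVER calibration and Fisher contrast ------------------------------

#: calibration study conditions: background fitted over a large gene
#: matrix with mostly low per-gene rates, as the method is used in practice
CALIBRATION_N_GENES = 100
CALIBRATION_N_SAMPLES = 600
CALIBRATION_RATE_RANGE = (0.03, 0.15)
CALIBRATION_DISPERSION = 0.4
CALIBRATION_N_PAIRS = 500


def discover_calibration_study(seed: int = 1) -> dict:
    """Null calibration of the margin-aware test plus planted-pair power.

    Under independence with heterogeneous per-sample rates the
    margin-aware exclusivity p-values should be near-uniform while
    Fisher exclusivity p-values are stochastically larger
    (conservative); a perfectly exclusive planted pair must reach a
    BH-adjusted p below 0.01.
    """
    from scipy.stats import kstest

    rng = np.random.default_rng(seed)
    rates = {
        f"G{i:03d}": r
        for i, r in enumerate(
            rng.uniform(*CALIBRATION_RATE_RANGE, CALIBRATION_N_GENES)
        )
    }
    _, truth = simulate_cohort(
        n_samples=CALIBRATION_N_SAMPLES,
        gene_rates=rates,
        sample_rate_dispersion=CALIBRATION_DISPERSION,
        tables=False,
        seed=seed + 1,
    )
    M = truth.alteration
    background = fit_background(M, tol=1e-8)
    genes = list(M.index)
    all_pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1:]]
    idx = rng.choice(len(all_pairs), CALIBRATION_N_PAIRS, replace=False)
    pairs = [all_pairs[i] for i in idx]
    discover_p = [
        discover_pair_test(M, background, a, b, "exclusive").p for a, b in pairs
    ]
    fisher_p = [fisher_pair_test(M, a, b, "exclusive").p for a, b in pairs]
    ks = kstest(discover_p, "uniform")

    # planted perfectly exclusive pair, rates 0.3/0.3, n=200
    planted_rates = {f"g{i}": r for i, r in
                     enumerate(np.random.default_rng(seed + 2).uniform(0.05, 0.3, 18))}
    planted_rates["GA"] = 0.3
    planted_rates["GB"] = 0.3
    _, ptruth = simulate_cohort(
        n_samples=200, gene_rates=planted_rates, sample_rate_dispersion=0.3,
        planted_pairs=[("GA", "GB", "exclusive", 1.0)], tables=False,
        seed=seed + 3,
    )
    pm = ptruth.alteration
    pgenes = list(pm.index)
    ppairs = [(a, b) for i, a in enumerate(pgenes) for b in pgenes[i + 1:]]
    screen = discover_screen({"all": pm}, ppairs, direction="exclusive")
    planted = next(r for r in screen if {r.gene_a, r.gene_b} == {"GA", "GB"})
    pbg = fit_background(pm)
    margin_resid = max(background.tol_achieved, pbg.tol_achieved)

    return {
        "ks_p": float(ks.pvalue),
        "ks_statistic": float(ks.statistic),
        "discover_mean_p": float(np.mean(discover_p)),
        "fisher_mean_p": float(np.mean(fisher_p)),
        "planted_pair_adjusted_p": float(planted.p_adjusted),
        "background_margin_residual": float(margin_resid),
        "n_pairs": len(pairs),
    }


def background_margin_study(seed: int = 1) -> dict:
    """Max expected-vs-observed margin residual over assorted matrices."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    shapes = [(10, 40), (25, 120), (60, 300)]
    for m, n in shapes:
        M = pd.DataFrame(
            (rng.random((m, n)) < rng.uniform(0.05, 0.4, (m, 1))).astype(np.int8)
        )
        bg = fit_background(M, tol=1e-8)
        A, P = M.to_numpy(), bg.p.to_numpy()
        worst = max(
            worst,
            float(np.abs(P.sum(1) - A.sum(1)).max()),
            float(np.abs(P.sum(0) - A.sum(0)).max()),
        )
    return {"max_margin_residual": worst}


# -- NNLS signature refitting ----------------------------------------------


def nnls_recovery_study(seed: int = 1, n_sims: int = 100,
                        n_mutations: int = 500) -> dict:
    """Exact-mixture recovery, resampling stability, optimizer cross-check."""
    rng = np.random.default_rng(seed)
    S = make_synthetic_signatures(("SIG-A", "SIG-B", "SIG-C", "SIG-D"), seed=96)
    Sm = S.to_numpy()

    exact = fit_signatures_nnls(
        pd.Series(Sm @ np.array([700.0, 300.0, 0, 0]), index=S.index), S
    )
    exact_err = float(
        np.abs(exact.exposures.to_numpy() - np.array([700, 300, 0, 0])).max()
    )

    true_e = np.array([0.5, 0.3, 0.2, 0.0])
    mix = Sm @ true_e
    cosines = []
    for _ in range(n_sims):
        spectrum = rng.poisson(mix * n_mutations)
        fit = fit_signatures_nnls(pd.Series(spectrum, index=S.index), S)
        e = fit.exposures.to_numpy()
        denom = np.linalg.norm(e) * np.linalg.norm(true_e)
        cosines.append(e @ true_e / denom if denom > 0 else 0.0)

    # projected-gradient oracle on random spectra
    StS = Sm.T @ Sm
    L = np.linalg.eigvalsh(StS).max()
    worst_obj = 0.0
    for _ in range(5):
        c = rng.random(96) * 20
        fit = fit_signatures_nnls(pd.Series(c, index=S.index), S)
        x = np.zeros(Sm.shape[1])
        for _ in range(20000):
            x = np.maximum(0.0, x - (StS @ x - Sm.T @ c) / L)
        worst_obj = max(
            worst_obj, abs(fit.residual_norm - np.linalg.norm(Sm @ x - c))
        )
    return {
        "exact_mixture_max_error": exact_err,
        "median_exposure_cosine": float(np.median(cosines)),
        "objective_vs_oracle_max_diff": float(worst_obj),
        "n_sims": n_sims,
    }


# -- survival oracles ------------------------------------------------------


def survival_oracle_study(seed: int = 1, n_null: int = 1000) -> dict:
    """KM closed form, log-rank null calibration, Cox identities/recovery."""
    rng = np.random.default_rng(seed)

    lam, n = 0.1, 1000
    t = rng.exponential(1 / lam, n)
    km = km_curve(t, np.ones(n, dtype=int))
    km_max_z = 0.0
    for q in np.quantile(t, [0.25, 0.5, 0.75]):
        s_hat, se = km.survival_at(q), km.se_at(q)
        km_max_z = max(km_max_z, abs(s_hat - math.exp(-lam * q)) / se)

    rejections = 0
    for _ in range(n_null):
        tt = rng.exponential(10.0, 200)
        g = np.repeat([0, 1], 100)
        rejections += logrank_test(tt, np.ones(200, dtype=int), g).p < 0.05

    t = rng.exponential(10, 300)
    e = rng.integers(0, 2, 300)
    x = rng.integers(0, 2, 300)
    fit = cox_ph_fit(t, e, pd.DataFrame({"x": x}))
    score_diff = abs(fit.score_chi2_at_zero - logrank_test(t, e, x).statistic)

    betas = []
    for _ in range(50):
        n2 = 2000
        x2 = rng.integers(0, 2, n2)
        te = rng.exponential(1 / (0.05 * np.exp(0.7 * x2)))
        tc = rng.exponential(np.quantile(te, 0.99) * 0.45, n2)  # ~20% censoring
        time, event = np.minimum(te, tc), (te <= tc).astype(int)
        betas.append(float(cox_ph_fit(time, event,
                                      pd.DataFrame({"x": x2})).coef["x"]))
    return {
        "km_max_z_at_quartiles": float(km_max_z),
        "logrank_null_rejection_rate": rejections / n_null,
        "cox_score_vs_logrank_diff": float(score_diff),
        "cox_beta_median": float(np.median(betas)),
        "cox_beta_median_abs_error": float(np.median(np.abs(np.array(betas) - 0.7))),
    }


# -- TMB arithmetic --------------------------------------------------------


def tmb_study(seed: int = 1) -> dict:
    """Printed per-platform Mb constants and z-score standardization."""
    rng = np.random.default_rng(seed)
    records = []
    for platform, version, n in (("WES", "", 40), ("MSK", "410", 30),
                                 ("Caris", "", 30)):
        for i in range(n):
            records.append(
                compute_tmb(int(rng.integers(1, 400)), platform, version,
                            sample=f"{platform}{i}")
            )
    out = harmonize_tmb(records)
    df = pd.DataFrame([r.__dict__ for r in out])
    grouped = df.groupby("platform")["z"]
    return {
        "wes_tmb_76_mutations": compute_tmb(76, "WES").tmb,
        "caris_tmb_14_mutations": compute_tmb(14, "Caris").tmb,
        "oncopanel_v3_tmb_10_mutations": compute_tmb(10, "Oncopanel", "v3").tmb,
        "z_mean_max_abs": float(grouped.mean().abs().max()),
        "z_sd_max_abs_error": float((grouped.std(ddof=1) - 1).abs().max()),
    }


# -- CLI determinism -------------------------------------------------------


def pipeline_determinism_study(seed: int = 1, depth: int = 500,
                               n_samples: int = 120) -> dict:
    """Byte-identity of the full CLI pipeline across two same-seed runs."""
    from click.testing import CliRunner

    from .cli import main as cli_main

    def run(out: Path) -> dict[str, bytes]:
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["all", "--out-dir", str(out), "--seed", str(seed),
             "--depth", str(depth), "--n-samples", str(n_samples)],
            catch_exceptions=False,
        )
        assert result.exit_code == 0, result.output
        return {
            str(p.relative_to(out)): p.read_bytes()
            for p in sorted(out.rglob("*"))
            if p.is_file()
        }

    with tempfile.TemporaryDirectory() as td:
        tree1 = run(Path(td) / "run1")
        tree2 = run(Path(td) / "run2")
    identical = tree1.keys() == tree2.keys() and all(
        tree1[k] == tree2[k] for k in tree1
    )
    return {"byte_identical": int(identical), "n_files": len(tree1)}
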