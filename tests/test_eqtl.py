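import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rpeqtl import eqtl, simgen
from rpeqtl.eqtl import (
    ExpressionMatrix,
    build_motif_inputs,
    cis_scan,
    delta_imbalance,
    hierarchical_fdr,
    multi_condition_fdr,
    select_covariates,
)
from rpeqtl.errors import ConfigurationError, ConsistencyError
from rpeqtl.mtc import bh_adjust, simes


class TestMtc:
    def test_simes_fixture(self):
        assert simes([0.01, 0.04, 0.9]) == pytest.approx(0.03)

    def test_simes_single(self):
        assert simes([0.2]) == pytest.approx(0.2)

    def test_bh_monotone(self):
        adj = bh_adjust([0.01, 0.02, 0.5, 0.9])
        assert np.all(np.diff(adj[np.argsort([0.01, 0.02, 0.5, 0.9])]) >= 0)
        assert np.all(adj <= 1)


def _sim(n=100, seed=3, beta=1.0, pi=0.75, n_loci=4, **kw):
    cfg = simgen.SimulationConfig(n_samples=n, n_loci=n_loci, seed=seed,
                                  depth_dispersion=0.02, ase_depth=80.0, **kw)
    cohort = simgen.simulate_cohort(cfg)
    truth = simgen.make_truth(cohort, beta=beta, pi=pi)
    counts, allelic = simgen.simulate_expression(cohort, truth)
    expr = ExpressionMatrix(counts=counts["glucose"],
                            tss=truth.genes[["gene_id", "chrom", "tss"]])
    return cohort, truth, expr, allelic["glucose"], counts, allelic


class TestCisScan:
    def test_planted_signal_strong(self):
        cohort, truth, expr, allelic, *_ = _sim(beta=2.0, pi=0.8)
        recs = cis_scan(expr, cohort.genotypes, allelic=allelic, condition="glucose")
        causal = truth.eqtl_effects.iloc[0]["causal_variant"]
        hit = recs[(recs["gene"] == "G0000") & (recs["variant_id"] == causal)]
        assert hit["p_combined"].iloc[0] < 1e-8

    def test_window_excludes_distant_variants(self):
        cohort, truth, expr, allelic, *_ = _sim(n=40)
        # shrink the window so only nearby variants are tested
        recs = cis_scan(expr, cohort.genotypes, window_bp=5_000)
        tssmap = truth.genes.set_index("gene_id")["tss"]
        vpos = cohort.genotypes.variants.set_index("variant_id")["pos"]
        dist = (recs["variant_id"].map(vpos) - recs["gene"].map(tssmap)).abs()
        assert (dist <= 5_000).all()
        full = cis_scan(expr, cohort.genotypes, window_bp=500_000)
        assert len(full) > len(recs)

    def test_null_p_combined_uniform(self):
        # single-gene null replicated across seeds; KS at alpha=0.01
        pvals = []
        for seed in range(300):
            cfg = simgen.SimulationConfig(n_samples=40, n_loci=3,
                                          variants_per_locus=3, seed=seed,
                                          depth_dispersion=0.02, ase_depth=80.0)
            cohort = simgen.simulate_cohort(cfg)
            truth = simgen.make_truth(cohort, beta=0.0, pi=0.5)
            counts, allelic = simgen.simulate_expression(cohort, truth)
            expr = ExpressionMatrix(counts=counts["glucose"],
                                    tss=truth.genes[["gene_id", "chrom", "tss"]])
            recs = cis_scan(expr, cohort.genotypes, allelic=allelic["glucose"])
            causal = truth.eqtl_effects.iloc[0]["causal_variant"]
            hit = recs[(recs["gene"] == "G0000") & (recs["variant_id"] == causal)]
            if not hit.empty:
                pvals.append(hit["p_combined"].iloc[0])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_pi_recovery_within_binomial_ci(self):
        cohort, truth, expr, allelic, *_ = _sim(n=100, n_loci=8, pi=0.7, seed=11)
        recs = cis_scan(expr, cohort.genotypes, allelic=allelic)
        ok = 0
        total = 0
        for _, eff in truth.eqtl_effects[truth.eqtl_effects["condition"] == "glucose"].iterrows():
            sub = allelic[(allelic["gene_id"] == eff["gene_id"])
                          & (allelic["variant_id"] == eff["causal_variant"])]
            alt, ref = sub["hap_alt_count"].sum(), sub["hap_ref_count"].sum()
            if alt + ref == 0:
                continue
            total += 1
            lo, hi = stats.binomtest(int(alt), int(alt + ref), 0.7).proportion_ci(0.95)
            rec = recs[(recs["gene"] == eff["gene_id"])
                       & (recs["variant_id"] == eff["causal_variant"])]
            if lo <= 0.7 <= hi or abs(rec["pi"].iloc[0] - 0.7) < 0.05:
                ok += 1
        assert total >= 5 and ok / total >= 0.95

    def test_sign_concordance(self):
        cohort, truth, expr, allelic, *_ = _sim(n=100, n_loci=8, beta=1.0, pi=0.75,
                                                seed=13)
        recs = cis_scan(expr, cohort.genotypes, allelic=allelic)
        causal = set(truth.eqtl_effects["causal_variant"])
        hits = recs[recs["variant_id"].isin(causal) & recs["pi"].notna()]
        conc = (np.sign(hits["beta"]) == np.sign(hits["pi"] - 0.5)).mean()
        assert conc >= 0.95

    def test_sample_mismatch_errors(self):
        cohort, truth, expr, allelic, *_ = _sim(n=20, n_loci=1)
        bad = ExpressionMatrix(counts=expr.counts.rename(columns={"S000": "zzz"}),
                               tss=truth.genes[["gene_id", "chrom", "tss"]])
        with pytest.raises(ConsistencyError):
            cis_scan(bad, cohort.genotypes)

    def test_rank_deficient_covariates_error(self):
        cohort, truth, expr, allelic, *_ = _sim(n=20, n_loci=1)
        cov = np.ones((20, 2))
        with pytest.raises(ConfigurationError):
            cis_scan(expr, cohort.genotypes, covariates=cov)


class TestHierarchicalFdr:
    def _records(self, p_by_gene):
        rows = []
        for gene, ps in p_by_gene.items():
            for i, p in enumerate(ps):
                rows.append({"gene": gene, "variant_id": f"{gene}_v{i}",
                             "chrom": "chr1", "pos": i, "condition": "c",
                             "beta": 0.0, "se": 1.0, "p_total": p, "p_ase": np.nan,
                             "p_combined": p, "pi": np.nan, "n_het": 0})
        return pd.DataFrame(rows)

    def test_all_ones_no_selection(self):
        calls = hierarchical_fdr(self._records({"g1": [1.0, 1.0], "g2": [1.0]}))
        assert calls.egenes == []
        assert calls.associations.empty

    def test_simes_gene_p(self):
        calls = hierarchical_fdr(self._records({"g1": [0.01, 0.04, 0.9]}))
        assert calls.genes["p_gene"].iloc[0] == pytest.approx(0.03)

    def test_hierarchy_respected(self):
        calls = hierarchical_fdr(self._records({
            "g1": [1e-8, 0.5], "g2": [0.9, 0.8], "g3": [1e-6, 1e-5]}))
        selected_genes = set(calls.egenes)
        assert set(calls.associations["gene"]) <= selected_genes

    def test_empty(self):
        calls = hierarchical_fdr(pd.DataFrame(columns=eqtl.ASSOCIATION_COLUMNS))
        assert calls.egenes == []


class TestMultiCondition:
    def _two_cond(self, pa, pb):
        def mk(ps, cond):
            rows = []
            for gene, plist in ps.items():
                for i, p in enumerate(plist):
                    rows.append({"gene": gene, "variant_id": f"{gene}_v{i}",
                                 "chrom": "chr1", "pos": i, "condition": cond,
                                 "beta": 0.0, "se": 1.0, "p_total": p,
                                 "p_ase": np.nan, "p_combined": p, "pi": np.nan,
                                 "n_het": 0})
            return pd.DataFrame(rows)
        return {"A": mk(pa, "A"), "B": mk(pb, "B")}

    def test_identical_records_shared(self):
        ps = {"g1": [1e-10, 1e-9], "g2": [0.5, 0.6]}
        calls = multi_condition_fdr(self._two_cond(ps, ps))
        g1 = calls.genes.set_index("gene").loc["g1"]
        assert g1["label"] == "shared"

    def test_condition_specific_label(self):
        calls = multi_condition_fdr(self._two_cond(
            {"g1": [1e-12, 1e-11]}, {"g1": [0.7, 0.9]}))
        assert calls.genes.set_index("gene").loc["g1", "label"] == "A-specific"

    def test_single_condition_delegates_with_warning(self):
        ps = {"g1": [1e-10]}
        with pytest.warns(UserWarning):
            calls = multi_condition_fdr({"A": self._two_cond(ps, ps)["A"]})
        assert calls.egenes == ["g1"]

    def test_planted_specific_recovered(self):
        hits = 0
        for seed in range(10):
            cfg = simgen.SimulationConfig(n_samples=80, n_loci=3, seed=seed,
                                          depth_dispersion=0.02, ase_depth=80.0)
            cohort = simgen.simulate_cohort(cfg)
            truth = simgen.make_truth(cohort, beta=1.5, pi=0.8,
                                      condition_specific_fraction=1.0)
            counts, allelic = simgen.simulate_expression(cohort, truth)
            records = {}
            for cond in ("glucose", "galactose"):
                expr = ExpressionMatrix(counts=counts[cond],
                                        tss=truth.genes[["gene_id", "chrom", "tss"]])
                records[cond] = cis_scan(expr, cohort.genotypes,
                                         allelic=allelic[cond], condition=cond)
            calls = multi_condition_fdr(records)
            labels = calls.genes.set_index("gene")["label"]
            if (labels == "glucose-specific").all():
                hits += 1
        assert hits >= 9


class TestDeltaImbalance:
    def _rec(self, pi, gene="g", vid="v"):
        return {"gene": gene, "variant_id": vid, "pi": pi}

    def test_examples(self):
        assert delta_imbalance(self._rec(0.8), self._rec(0.5)) == pytest.approx(0.3)
        assert delta_imbalance(self._rec(0.2), self._rec(0.8)) == pytest.approx(0.0)
        assert delta_imbalance(self._rec(0.66), self._rec(0.66)) == 0.0

    def test_missing_pi_nan(self):
        assert np.isnan(delta_imbalance(self._rec(np.nan), self._rec(0.5)))

    def test_mismatch_errors(self):
        with pytest.raises(ConsistencyError):
            delta_imbalance(self._rec(0.5, gene="a"), self._rec(0.5, gene="b"))


class TestSelectCovariates:
    def test_confounder_improves_and_deterministic(self):
        rng = np.random.default_rng(0)
        n = 80
        cfg = simgen.SimulationConfig(n_samples=n, n_loci=6, seed=21,
                                      depth_dispersion=0.02)
        cohort = simgen.simulate_cohort(cfg)
        truth = simgen.make_truth(cohort, beta=0.6, pi=0.6)
        counts, allelic = simgen.simulate_expression(cohort, truth)
        conf = rng.standard_normal(n)
        confounded = (counts["glucose"] * np.power(2.0, 1.5 * conf)).round().astype(int)
        expr = ExpressionMatrix(counts=confounded,
                                tss=truth.genes[["gene_id", "chrom", "tss"]])
        candidates = [("confounder", conf)]
        chosen, diag = select_covariates(expr, cohort.genotypes,
                                         candidates, probe_genes=6, seed=5)
        assert chosen == ["confounder"]
        counts_by_k = diag.set_index("n_covariates")["n_associations"]
        assert counts_by_k.loc[1] > counts_by_k.loc[0]
        chosen2, diag2 = select_covariates(expr, cohort.genotypes,
                                           candidates, probe_genes=6, seed=5)
        assert chosen2 == chosen and diag2.equals(diag)

    def test_collinear_candidate_dropped(self):
        cohort, truth, expr, allelic, *_ = _sim(n=30, n_loci=2, seed=2)
        v = np.arange(30, dtype=float)
        with pytest.warns(UserWarning, match="collinear"):
            chosen, diag = select_covariates(
                expr, cohort.genotypes, [("a", v), ("a_dup", 2 * v)],
                probe_genes=2, seed=1)
        assert diag["n_covariates"].max() == 1

    def test_noise_candidates_prefer_smaller_set(self):
        cohort, truth, expr, allelic, *_ = _sim(n=40, n_loci=2, seed=8, beta=0.0,
                                                pi=0.5)
        rng = np.random.default_rng(4)
        cands = [(f"n{i}", rng.standard_normal(40)) for i in range(2)]
        chosen, diag = select_covariates(expr, cohort.genotypes, cands,
                                         probe_genes=2, seed=2)
        best = diag["n_associations"].max()
        smallest_best = diag[diag["n_associations"] == best]["n_covariates"].min()
        assert len(chosen) == smallest_best


class TestMotifInputs:
    def _records(self, beta):
        return pd.DataFrame({
            "gene": ["g"], "variant_id": ["v1"], "chrom": ["chr1"], "pos": [20],
            "ref": ["A"], "alt": ["G"], "beta": [beta]})

    def test_positive_beta_alt_target(self):
        ref = {"chr1": "ACGT" * 20}
        targets, backgrounds = build_motif_inputs(self._records(1.0), ref, flank=15)
        assert len(targets[0][1]) == 31
        assert targets[0][1][15] == "G"
        assert backgrounds[0][1][15] == "A"

    def test_negative_beta_swaps(self):
        ref = {"chr1": "ACGT" * 20}
        targets, backgrounds = build_motif_inputs(self._records(-1.0), ref, flank=15)
        assert targets[0][1][15] == "A"
        assert backgrounds[0][1][15] == "G"

    def test_edge_variant_skipped(self):
        ref = {"chr1": "ACGTACGTAC"}
        targets, backgrounds = build_motif_inputs(self._records(1.0), ref, flank=15)
        assert targets == [] and backgrounds == []
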