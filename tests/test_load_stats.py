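"""Load statistics: degeneracy, diversity, ROH, polarization, burden ratios."""

import numpy as np
import pandas as pd
import pytest

from purgekit.load_stats import (
    classify_degeneracy,
    count_derived,
    detect_roh,
    f_roh,
    individual_heterozygosity,
    inbreeding_f_het,
    ld_decay,
    load_ratios,
    pi_by_site_class,
    pi_ratio_0fold_4fold,
    polarize_sites,
    roh_stratified_ratios,
    welch_compare,
    windowed_pi,
)

from conftest import build_dataset
from _oracles import GENETIC_CODE, degeneracy_oracle


# ---------------------------------------------------------------------------
# degeneracy


def _write_toy_annotation(tmp_path, seq, strand="+", name="tx1"):
    fasta = tmp_path / "genome.fa"
    gff = tmp_path / "genes.gff3"
    fasta.write_text(f">chr1\n{seq}\n")
    gff.write_text(
        "##gff-version 3\n"
        f"chr1\t.\tgene\t1\t{len(seq)}\t.\t{strand}\t.\tID=g1\n"
        f"chr1\t.\tmRNA\t1\t{len(seq)}\t.\t{strand}\t.\tID={name};Parent=g1\n"
        f"chr1\t.\tCDS\t1\t{len(seq)}\t.\t{strand}\t0\tID=cds1;Parent={name}\n"
    )
    return fasta, gff


class TestDegeneracy:
    def test_known_codon_positions(self, tmp_path):
        # GGT third position is 4-fold (all GGN = Gly); second positions 0-fold
        fasta, gff = _write_toy_annotation(tmp_path, "GGTATG")
        out = classify_degeneracy(fasta, gff)
        fold = out.set_index("pos")["fold"]
        assert fold[3] == "4"      # GGT wobble
        assert fold[2] == "0"      # no second-position synonymy
        assert fold[5] == "0"      # ATG is non-degenerate everywhere
        assert out.attrs["skipped"] == []

    def test_full_codon_table_both_strands_matches_oracle(self, tmp_path):
        """All sense codons x 3 positions agree with the frozen code table,
        on the forward and the reverse strand."""
        sense = [c for c in sorted(GENETIC_CODE) if GENETIC_CODE[c] != "*"]
        seq_fwd = "".join(sense)
        comp = str.maketrans("ACGT", "TGCA")
        for strand, seq in (("+", seq_fwd), ("-", seq_fwd.translate(comp)[::-1])):
            fasta, gff = _write_toy_annotation(tmp_path, seq, strand=strand)
            out = classify_degeneracy(fasta, gff)
            assert len(out) == 3 * len(sense)
            for row in out.itertuples(index=False):
                assert row.fold == degeneracy_oracle(row.codon, row.codon_pos), (
                    row.codon, row.codon_pos, strand
                )

    def test_internal_stop_skips_transcript(self, tmp_path):
        fasta, gff = _write_toy_annotation(tmp_path, "ATGTAAGGT")
        out = classify_degeneracy(fasta, gff)
        assert len(out) == 0
        assert "internal stop" in out.attrs["skipped"][0][1]

    def test_frame_violation_skips_transcript(self, tmp_path):
        fasta, gff = _write_toy_annotation(tmp_path, "ATGGG")
        out = classify_degeneracy(fasta, gff)
        assert len(out) == 0
        assert "divisible by 3" in out.attrs["skipped"][0][1]


# ---------------------------------------------------------------------------
# diversity


class TestWindowedPi:
    def test_monomorphic_window_is_zero(self):
        ds = build_dataset(np.zeros((3, 4), dtype=np.int8), contig_length=1000)
        out = windowed_pi(ds, window=1000, step=1000)
        assert out["pi"].iloc[0] == 0.0

    def test_two_haplotype_hand_calculation(self):
        """One heterozygous diploid: j=1 of n=2 alleles -> pi = 1 per site."""
        ds = build_dataset([[1]], positions=[500], contig_length=1000)
        out = windowed_pi(ds, window=1000, step=1000)
        assert out["pi"].iloc[0] == pytest.approx(1.0 / 1000)

    def test_two_diploid_hand_calculation(self):
        """Genotypes 0/0 and 1/1: j=2 of n=4 -> unbiased pi = 2/3 per site."""
        ds = build_dataset([[0, 2]], positions=[500], contig_length=1000)
        out = windowed_pi(ds, window=1000, step=1000)
        assert out["pi"].iloc[0] == pytest.approx((2 / 3) / 1000)

    def test_empty_window_flagged_na(self):
        ds = build_dataset([[1]], positions=[100], contig_length=30_000)
        out = windowed_pi(ds, window=10_000, step=10_000)
        assert out["pi"].iloc[1:].isna().all()


class TestHeterozygosity:
    def test_arithmetic(self):
        G = np.zeros((7, 2), dtype=np.int8)
        G[:5, 0] = 1
        ds = build_dataset(G, contig_length=10_000)
        het = individual_heterozygosity(ds)
        assert het.iloc[0] == pytest.approx(5e-4)
        assert het.iloc[1] == 0.0

    def test_mean_heterozygosity_tracks_pi_under_hw(self, small_config):
        """Without implanted autozygosity, individual het ~ population pi."""
        import copy

        from purgekit.load_stats import _site_pi
        from purgekit.synthetic_data import generate_cohort

        cfg = copy.deepcopy(small_config)
        for p in cfg.populations:
            p.roh_target_mean = 0.0
            p.roh_target_sd = 0.0
        ds = generate_cohort(cfg, seed=9)
        for sp in ("rare", "widespread"):
            cols = np.flatnonzero((ds.individuals["species"] == sp).to_numpy())
            pi = _site_pi(ds.genotypes[:, cols]).sum() / ds.genome_length
            het = individual_heterozygosity(ds).iloc[cols].mean()
            assert het == pytest.approx(pi, rel=0.10)

    def test_f_het_positive_for_autozygous_individuals(self, small_cohort):
        f = inbreeding_f_het(small_cohort)
        assert f.mean() > 0


class TestPiByClass:
    def test_equal_classes_give_ratio_one(self):
        G = np.tile(np.array([[0, 1, 2, 1]], dtype=np.int8), (4, 1))
        ds = build_dataset(G, effect_class=["a", "a", "b", "b"])
        mask_a = (ds.sites["effect_class"] == "a").to_numpy()
        mask_b = (ds.sites["effect_class"] == "b").to_numpy()
        pa = pi_by_site_class(ds, mask_a, 100, by_population=False)
        pb = pi_by_site_class(ds, mask_b, 100, by_population=False)
        assert pa["all"] == pytest.approx(pb["all"])

    def test_selected_class_shows_reduced_diversity(self, small_cohort,
                                                    small_config):
        """pi per mutational opportunity is lower for the recessive-deleterious
        class than for synonymous sites (purifying selection signature)."""
        s_mask = (small_cohort.sites["effect_class"] == "synonymous").to_numpy()
        d_mask = (small_cohort.sites["effect_class"] == "deleterious").to_numpy()
        ps = pi_by_site_class(small_cohort, s_mask,
                              small_config.class_budgets["synonymous"])
        pd_ = pi_by_site_class(small_cohort, d_mask,
                               small_config.class_budgets["deleterious"])
        assert (pd_ / ps < 1).all()

    def test_degeneracy_map_ratio(self, tmp_path):
        # two sites: one 0-fold, one 4-fold, same genotype column
        degmap = pd.DataFrame(
            {"contig": ["chr1", "chr1"], "pos": [1000, 2000],
             "transcript": ["t", "t"], "codon": ["GGT", "GGT"],
             "codon_pos": [1, 2], "fold": ["0", "4"]}
        )
        G = np.array([[0, 1, 1, 0], [0, 1, 1, 0]], dtype=np.int8)
        ds = build_dataset(G, positions=[1000, 2000])
        out = pi_ratio_0fold_4fold(ds, degmap)
        assert out["ratio"].iloc[0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# ROH


class TestDetectRoh:
    def test_regular_heterozygosity_yields_no_roh(self):
        rng = np.random.default_rng(0)
        n_sites = 500
        G = rng.binomial(2, 0.5, size=(n_sites, 6)).astype(np.int8)
        G[::10, 0] = 1  # focal individual het every 10th site, hom elsewhere
        ds = build_dataset(G, positions=np.arange(1, n_sites + 1) * 1000,
                           contig_length=n_sites * 1000)
        segs = detect_roh(ds, min_length=100_000)
        assert (segs["individual"] != "ind0").all() or len(segs) == 0

    def test_implanted_two_megabase_tract_recovered(self):
        rng = np.random.default_rng(1)
        n_sites, spacing = 5000, 1000
        q = rng.uniform(0.2, 0.5, n_sites)
        G = rng.binomial(2, q[:, None], size=(n_sites, 8)).astype(np.int8)
        pos = np.arange(1, n_sites + 1) * spacing
        start, end = 1_500_000, 3_499_999
        inside = (pos >= start) & (pos <= end)
        G[inside, 0] = np.where(rng.random(inside.sum()) < q[inside], 2, 0)
        ds = build_dataset(G, positions=pos, contig_length=n_sites * spacing)
        segs = detect_roh(ds, min_length=100_000)
        mine = segs[segs["individual"] == "ind0"]
        assert len(mine) == 1
        ov = min(mine["end"].iloc[0], end) - max(mine["start"].iloc[0], start) + 1
        assert ov / (end - start + 1) >= 0.9
        assert ov / mine["length"].iloc[0] >= 0.9
        assert bool(mine["is_long"].iloc[0])

    def test_unsorted_input_rejected(self, small_cohort):
        broken = small_cohort.subset_sites(np.arange(small_cohort.n_sites))
        pos = broken.sites["pos"].to_numpy().copy()
        pos[0], pos[1] = pos[1], pos[0]
        broken.sites["pos"] = pos
        with pytest.raises(ValueError, match="sorted"):
            detect_roh(broken)


class TestFRoh:
    def test_no_segments_zero(self):
        segs = pd.DataFrame(columns=["individual", "contig", "start", "end",
                                     "length", "n_sites", "is_long"])
        out = f_roh(segs, 100_000_000, individuals=["a"])
        assert out["a"] == 0.0

    def test_fraction_arithmetic(self):
        segs = pd.DataFrame(
            [{"individual": "a", "contig": "c", "start": 1,
              "end": 10_000_000, "length": 10_000_000, "n_sites": 10,
              "is_long": True}]
        )
        assert f_roh(segs, 100_000_000)["a"] == pytest.approx(0.1)
        assert f_roh(segs, 100_000_000, long_only=True)["a"] == pytest.approx(0.1)

    def test_overlap_is_an_invariant_breach(self):
        segs = pd.DataFrame(
            [
                {"individual": "a", "contig": "c", "start": 1, "end": 200_000,
                 "length": 200_000, "n_sites": 5, "is_long": False},
                {"individual": "a", "contig": "c", "start": 150_000,
                 "end": 400_000, "length": 250_001, "n_sites": 5,
                 "is_long": False},
            ]
        )
        with pytest.raises(ValueError, match="overlap"):
            f_roh(segs, 1_000_000)


# ---------------------------------------------------------------------------
# polarization and burden


class TestPolarize:
    def test_agreeing_outgroups_set_alt_derived(self):
        ds = build_dataset([[1]], ref="A", alt="G", outgroups=("A", "A"))
        out = polarize_sites(ds.sites)
        assert out["polarized"].iloc[0]
        assert out["derived_is_alt"].iloc[0]

    def test_conflicting_outgroups_unpolarized(self):
        ds = build_dataset([[1]], ref="A", alt="G", outgroups=("A", "G"))
        out = polarize_sites(ds.sites)
        assert not out["polarized"].iloc[0]
        assert out["status"].iloc[0] == "conflict"

    def test_double_mismatch_unpolarized(self):
        ds = build_dataset([[1]], ref="A", alt="G", outgroups=("T", "T"))
        out = polarize_sites(ds.sites)
        assert out["status"].iloc[0] == "mismatch"

    def test_relaxed_mode_uses_single_outgroup(self):
        ds = build_dataset([[1]], ref="A", alt="G", outgroups=("G", "."))
        strict = polarize_sites(ds.sites, mode="strict")
        relaxed = polarize_sites(ds.sites, mode="relaxed")
        assert not strict["polarized"].iloc[0]
        assert relaxed["polarized"].iloc[0]
        assert relaxed["status"].iloc[0] == "single_outgroup"
        assert not relaxed["derived_is_alt"].iloc[0]  # outgroup carries ALT

    def test_misassignment_below_five_percent_on_synthetic_truth(
        self, small_cohort
    ):
        out = polarize_sites(small_cohort.sites)
        assigned = out["polarized"]
        wrong = assigned & (out["anc_call"] != small_cohort.sites["anc_truth"])
        assert wrong.sum() / assigned.sum() < 0.05


class TestCountDerived:
    @pytest.mark.parametrize("g,alt_derived,expected",
                             [(2, True, 2), (1, True, 1), (0, True, 0),
                              (2, False, 0), (0, False, 2), (-1, True, 0)])
    def test_rule(self, g, alt_derived, expected):
        assert count_derived(g, alt_derived) == expected

    def test_invalid_genotype_rejected(self):
        with pytest.raises(ValueError):
            count_derived(3)


class TestLoadRatios:
    def hand_fixture(self):
        """3 individuals x 8 sites with pencil-and-paper expected ratios."""
        #                 ind0 ind1 ind2
        G = np.array([
            [1, 0, 2],   # syn
            [1, 1, 0],   # syn
            [2, 0, 0],   # syn
            [0, 2, 1],   # syn (REF derived at this site: anc = ALT)
            [1, 0, 1],   # del
            [2, 1, 0],   # del
            [0, 1, -1],  # del (missing for ind2)
            [1, 2, 0],   # LoF
        ], dtype=np.int8)
        classes = ["synonymous"] * 4 + ["deleterious"] * 3 + ["LoF"]
        # outgroups match REF everywhere except site 3 where they match ALT
        og = np.array(["A"] * 8)
        og[3] = "G"
        ds = build_dataset(G, effect_class=classes, ref="A", alt="G",
                           outgroups=(og, og.copy()))
        return ds

    def test_exact_ratios_on_hand_fixture(self):
        ds = self.hand_fixture()
        pol = polarize_sites(ds.sites)
        tab = load_ratios(ds, pol)
        t = tab.set_index(["individual", "effect_class"])
        # ind0: syn derived: site0 het, site1 het, site2 hom, site3 anc=G ->
        #   dosage 0 -> derived 2 (hom). syn het = 2, syn hom sites = 2
        # del: site4 het, site5 hom, site6 anc-hom -> het 1, hom 1
        assert t.loc[("ind0", "deleterious"), "het_ratio"] == pytest.approx(1 / 2)
        assert t.loc[("ind0", "deleterious"), "hom_ratio"] == pytest.approx(
            2 / 4
        )
        # ind2: syn: site0 hom(2), site3 genotype 1 -> derived het 1
        #   -> syn het 1, syn hom 1; del: site4 het 1, site6 missing
        assert t.loc[("ind2", "deleterious"), "het_ratio"] == pytest.approx(1.0)
        assert t.loc[("ind2", "deleterious"), "hom_ratio"] == pytest.approx(0.0)
        # ind1: LoF hom 1 -> 2/derived syn hom: site3 dosage 2 -> derived 0!
        #   syn hom for ind1: site3 dosage 2 means hom-ALT but anc=ALT -> 0
        #   derived syn hom count = 0 -> hom ratio NaN
        assert np.isnan(t.loc[("ind1", "LoF"), "hom_ratio"])

    def test_ratio_invariant_to_hom_ancestral_sites(self):
        ds = self.hand_fixture()
        pol = polarize_sites(ds.sites)
        base = load_ratios(ds, pol)
        # append sites where everyone is hom-ancestral
        extra = np.zeros((4, 3), dtype=np.int8)
        G2 = np.vstack([ds.genotypes, extra])
        classes2 = list(ds.sites["effect_class"]) + \
            ["synonymous", "deleterious", "LoF", "tolerated"]
        ds2 = build_dataset(G2, effect_class=classes2, ref="A", alt="G",
                            outgroups=(["A"] * 12, ["A"] * 12))
        ds2.sites.loc[3, ["outgroup1", "outgroup2"]] = "G"
        pol2 = polarize_sites(ds2.sites)
        tab2 = load_ratios(ds2, pol2)
        for col in ("het_ratio", "hom_ratio"):
            pd.testing.assert_series_equal(base[col], tab2[col],
                                           check_names=False)


class TestRohStratified:
    def test_no_roh_outside_equals_totals(self):
        ds = TestLoadRatios().hand_fixture()
        pol = polarize_sites(ds.sites)
        segs = pd.DataFrame(columns=["individual", "contig", "start", "end",
                                     "length", "n_sites", "is_long"])
        out = roh_stratified_ratios(ds, segs, pol)
        tot = load_ratios(ds, pol)
        m = out.merge(tot, on=["individual", "effect_class"])
        assert (m["in_count"] == 0).all()
        assert (m["out_count"] == m["het_count"] + m["hom_count"]).all()

    def test_single_site_roh_hand_count(self):
        ds = TestLoadRatios().hand_fixture()
        pol = polarize_sites(ds.sites)
        # ROH of ind0 covering only site 5 (pos 6000, deleterious, dosage 2)
        segs = pd.DataFrame(
            [{"individual": "ind0", "contig": "chr1", "start": 5500,
              "end": 6500, "length": 1001, "n_sites": 1, "is_long": False}]
        )
        out = roh_stratified_ratios(ds, segs, pol).set_index(
            ["individual", "effect_class"]
        )
        assert out.loc[("ind0", "deleterious"), "in_count"] == 2
        assert out.loc[("ind0", "deleterious"), "out_count"] == 1
        assert out.loc[("ind0", "LoF"), "in_count"] == 0

    def test_partition_in_plus_out_equals_total(self, small_cohort):
        pol = polarize_sites(small_cohort.sites)
        segs = detect_roh(small_cohort, min_length=20_000)
        strat = roh_stratified_ratios(small_cohort, segs, pol)
        tot = load_ratios(small_cohort, pol)
        m = strat.merge(tot, on=["individual", "effect_class"])
        assert (
            m["in_count"] + m["out_count"] == m["het_count"] + m["hom_count"]
        ).all()


class TestWelch:
    def test_separated_groups_give_small_p(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame(
            {
                "species": ["a"] * 20 + ["b"] * 20,
                "effect_class": "deleterious",
                "het_ratio": np.concatenate(
                    [rng.normal(0.5, 0.05, 20), rng.normal(0.8, 0.05, 20)]
                ),
            }
        )
        out = welch_compare(tab, "het_ratio")
        assert out["p"].iloc[0] < 1e-6


class TestLdDecay:
    def test_duplicate_site_perfect_ld_at_zero_distance(self):
        rng = np.random.default_rng(0)
        col = rng.binomial(2, 0.4, 40).astype(np.int8)
        ds = build_dataset(np.vstack([col, col]), positions=[1000, 2000],
                           contig_length=10_000)
        out = ld_decay(ds, max_dist=10_000, bin_width=10_000)
        assert out["mean_r2"].iloc[0] == pytest.approx(1.0)

    def test_independent_sites_mean_r2_near_one_over_n(self):
        rng = np.random.default_rng(1)
        n = 100
        G = rng.binomial(2, 0.5, size=(300, n)).astype(np.int8)
        ds = build_dataset(G, positions=np.arange(1, 301) * 100,
                           contig_length=100_000)
        out = ld_decay(ds, max_dist=100_000, bin_width=100_000)
        assert out["mean_r2"].iloc[0] == pytest.approx(1 / n, rel=0.25)
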