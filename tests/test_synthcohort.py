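import numpy as np
import pytest
from scipy import stats

import introcap as ic
from introcap.synthcohort import (
    DELETION,
    HOM_REF,
    MISSING,
    read_genotype_tsv,
    write_genotype_tsv,
)


class TestMakeReference:
    def test_lengths_and_centromere_placement(self):
        ref = ic.make_reference([7_000_000], [0.48], seed=42)
        assert ref.length("chr1") == 7_000_000
        assert ref.centromeres["chr1"] == 3_360_000

    def test_seeded_determinism(self):
        a = ic.make_reference([50_000], [0.5], seed=42)
        b = ic.make_reference([50_000], [0.5], seed=42)
        assert np.array_equal(a.chromosomes["chr1"], b.chromosomes["chr1"])

    def test_base_composition_uniform(self):
        # each base frequency within 3 binomial SD of 1/4 over 1 Mb
        L = 1_000_000
        ref = ic.make_reference([L], [0.5], seed=7)
        sd = np.sqrt(0.25 * 0.75 / L)
        freqs = np.bincount(ref.chromosomes["chr1"], minlength=4) / L
        assert np.all(np.abs(freqs - 0.25) <= 3 * sd)

    @pytest.mark.parametrize("bad", [([0], [0.5]), ([-5], [0.5]), ([100], [1.0])])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            ic.make_reference(bad[0], bad[1], seed=1)


class TestMakeDonor:
    def test_zero_divergence_is_identity(self):
        ref = ic.make_reference([20_000], [0.5], seed=3)
        donor = ic.make_donor(ref, ic.DonorSpec("d", "primary", 0.0, 0.0, 5))
        assert np.array_equal(donor.chromosomes["chr1"], ref.chromosomes["chr1"])

    def test_divergence_calibration(self):
        # realized substitution fraction within 3 binomial SD of d over 1 Mb
        L = 1_000_000
        d = 0.12
        ref = ic.make_reference([L], [0.5], seed=4)
        donor = ic.make_donor(ref, ic.DonorSpec("d", "tertiary", d, 0.0, 6))
        observed = np.mean(ref.chromosomes["chr1"] != donor.chromosomes["chr1"])
        assert abs(observed - d) <= 3 * np.sqrt(d * (1 - d) / L)

    def test_no_indels_preserves_length(self):
        ref = ic.make_reference([30_000], [0.5], seed=5)
        donor = ic.make_donor(ref, ic.DonorSpec("d", "secondary", 0.06, 0.0, 7))
        assert len(donor.chromosomes["chr1"]) == 30_000

    def test_indels_change_length_and_lift_tracks_them(self):
        ref = ic.make_reference([100_000], [0.5], seed=8)
        donor = ic.make_donor(ref, ic.DonorSpec("d", "tertiary", 0.0, 1e-3, 9))
        assert len(donor.chromosomes["chr1"]) != 100_000
        # with zero substitutions the lifted slice should be near-identical
        # to the reference away from indel breakpoints
        sl = donor.slice("chr1", 1_000, 2_000)
        ref_sl = ref.chromosomes["chr1"][1_000:2_000]
        n = min(len(sl), len(ref_sl))
        # identity over the aligned prefix is high unless an indel hit it
        assert np.mean(sl[:n] == ref_sl[:n]) > 0.5

    def test_excessive_divergence_rejected(self):
        with pytest.raises(ValueError):
            ic.DonorSpec("d", "primary", 1.5, 0.0, 1)


class TestMakeAccession:
    def test_no_segments_equals_reference(self, small_cohort):
        ref, donors, _ = small_cohort
        mosaic = ic.make_accession(ref, donors, [], "X")
        for chrom in ref.names:
            assert np.array_equal(mosaic.chromosomes[chrom], ref.chromosomes[chrom])

    def test_divergence_confined_to_segment(self, small_cohort):
        ref, donors, mosaic = small_cohort
        chr1_ref = ref.chromosomes["chr1"]
        chr1_mos = mosaic.chromosomes["chr1"]
        assert len(chr1_mos) == len(chr1_ref)
        inside = np.mean(chr1_ref[:100_000] != chr1_mos[:100_000])
        assert abs(inside - 0.12) < 0.02
        # truth consistency: identical outside the segment
        assert np.array_equal(chr1_ref[100_000:], chr1_mos[100_000:])

    def test_overlapping_segments_rejected(self, small_cohort):
        ref, donors, _ = small_cohort
        segs = [
            ic.IntrogressionSegment("chr1", 0, 1000, "tertiary"),
            ic.IntrogressionSegment("chr1", 500, 2000, "primary"),
        ]
        with pytest.raises(ValueError):
            ic.make_accession(ref, donors, segs, "X")

    def test_deletion_removes_sequence_and_lift_is_recorded(self, small_cohort):
        ref, donors, _ = small_cohort
        segs = [ic.IntrogressionSegment("chr1", 10_000, 20_000, DELETION)]
        mosaic = ic.make_accession(ref, donors, segs, "X")
        assert mosaic.length("chr1") == ref.length("chr1") - 10_000
        # positions after the deletion shift left by its length
        assert mosaic.lift_interval("chr1", 30_000, 40_000) == (20_000, 30_000)
        # sequence after the deletion is the reference sequence
        assert np.array_equal(
            mosaic.chromosomes["chr1"][10_000:20_000],
            ref.chromosomes["chr1"][20_000:30_000],
        )


class TestDesignProbes:
    def test_exact_probe_count(self, small_cohort):
        ref = small_cohort[0]
        probes = ic.design_probes(ref, 500, 120, 2.0, seed=1)
        assert len(probes) == 500
        assert (probes.probes["end"] - probes.probes["start"]).eq(120).all()

    def test_negative_density_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            ic.design_probes(small_cohort[0], 10, 120, -1.5, seed=1)

    def test_zero_slope_positions_uniform(self):
        # chi-square GOF over 10 equal bins, not rejected at alpha = 0.01
        ref = ic.make_reference([1_000_000], [0.5], seed=1)
        probes = ic.design_probes(ref, 2000, 120, 0.0, seed=42)
        counts, _ = np.histogram(probes.probes["start"], bins=10, range=(0, 1_000_000))
        _, p = stats.chisquare(counts)
        assert p > 0.01

    def test_positive_slope_enriches_telomeres(self):
        # distal deciles denser than centromere-flanking deciles, 20 seeds
        ref = ic.make_reference([500_000], [0.5], seed=2)
        cen = ref.centromeres["chr1"]
        distal, proximal = 0, 0
        for seed in range(20):
            probes = ic.design_probes(ref, 400, 120, 3.0, seed=seed)
            pos = probes.probes["start"].to_numpy()
            arm_len = np.where(pos < cen, cen, ref.length("chr1") - cen)
            x = np.abs(pos - cen) / arm_len
            distal += int((x > 0.8).sum())
            proximal += int((x < 0.2).sum())
        assert distal / 20 > proximal / 20


class TestSimulateGenotypes:
    def test_reference_accession_is_hom_ref(self, small_cohort):
        ref, donors, _ = small_cohort
        plain = ic.make_accession(ref, donors, [], "P")
        gm = ic.simulate_genotypes(ref, [plain], 200, 0.0, 0.0, seed=1)
        assert (gm.calls["P"] == HOM_REF).all()

    def test_deletion_markers_are_missing(self, small_cohort):
        ref, donors, _ = small_cohort
        segs = [ic.IntrogressionSegment("chr1", 0, 150_000, DELETION)]
        mosaic = ic.make_accession(ref, donors, segs, "D")
        gm = ic.simulate_genotypes(ref, [mosaic], 400, 0.0, 0.0, seed=2)
        inside = gm.subset("chr1", 0, 150_000)
        assert len(inside) > 0
        assert (gm.calls.loc[inside, "D"] == MISSING).all()

    def test_introgressed_markers_mostly_hom_alt(self, small_cohort):
        ref, donors, mosaic = small_cohort
        gm = ic.simulate_genotypes(ref, [mosaic], 600, 0.0, 0.0, seed=3)
        inside = gm.subset("chr1", 0, 100_000)
        frac_alt = (gm.calls.loc[inside, "ACC1"] == 1).mean()
        assert 0.75 < frac_alt <= 1.0

    def test_invalid_rates_rejected(self, small_cohort):
        ref = small_cohort[0]
        with pytest.raises(ValueError):
            ic.simulate_genotypes(ref, [], 10, err_rate=1.5, seed=1)

    def test_genotype_tsv_roundtrip(self, small_cohort, tmp_path):
        ref, donors, mosaic = small_cohort
        gm = ic.simulate_genotypes(ref, [mosaic], 100, 0.05, 0.05, seed=4)
        path = tmp_path / "geno.tsv"
        write_genotype_tsv(path, gm)
        back = read_genotype_tsv(path)
        assert back.accessions == gm.accessions
        assert (back.calls.to_numpy() == gm.calls.to_numpy()).all()
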