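"""Distance D, heterozygosity, Weir-Cockerham Fst, pseudo-diploids, folded AFS."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hybridscope.divergence import (
    folded_afs,
    fst_wc,
    heterozygosity_windows,
    pair_pi,
    pseudo_diploid,
)
from hybridscope.genotypes import MISSING, VariantMatrix, make_windows
from hybridscope.sim import PopulationModel


def matrix_from_genotypes(geno, length=1_000_000):
    geno = np.asarray(geno, dtype=np.int8)
    m = geno.shape[1]
    pos = np.linspace(1, length - 1, m, dtype=int)
    pos = np.unique(pos)[:m]
    sites = pd.DataFrame({"chrom": "chr1", "pos": pos, "ref": "A", "alt": "T",
                          "callable": True})
    samples = pd.DataFrame({"id": [f"s{i}" for i in range(geno.shape[0])]})
    return VariantMatrix(sites, geno, samples, chrom_lengths={"chr1": length})


class TestPairPi:
    def test_site_contributions_brute_force(self):
        """pi12 per-site contribution equals the enumeration over random
        allele draws for all 9 genotype pairs."""
        for g1, g2 in itertools.product([0, 1, 2], repeat=2):
            m = matrix_from_genotypes([[g1], [g2]])
            frame = make_windows(m, "bp_span", 10**6)
            res = pair_pi(m, 0, 1, frame)
            # enumeration: draw one allele from each diploid, P(different)
            a1 = [0] * (2 - g1) + [1] * g1
            a2 = [0] * (2 - g2) + [1] * g2
            expect = np.mean([x != y for x in a1 for y in a2])
            assert res.genome_pi12 == pytest.approx(expect)

    def test_het_pair_contributes_half(self):
        m = matrix_from_genotypes([[1], [1]])
        frame = make_windows(m, "bp_span", 10**6)
        assert pair_pi(m, 0, 1, frame).genome_pi12 == pytest.approx(0.5)

    def test_missing_sites_excluded_everywhere(self):
        m = matrix_from_genotypes([[1, 1, MISSING], [1, MISSING, 1]])
        frame = make_windows(m, "bp_span", 10**6)
        res = pair_pi(m, 0, 1, frame)
        assert res.n_used == 1
        assert res.genome_pi1 == res.genome_pi2 == 1.0

    def test_identical_diploids_relation(self, small_cohort):
        """For identical genomes pi12 = pi1/2 = pi2/2 (hence D = 0)."""
        matrix, _ = small_cohort
        frame = make_windows(matrix, "bp_span", 500_000)
        res = pair_pi(matrix, "F1", "F1c", frame)
        assert res.genome_pi12 == pytest.approx(res.genome_pi1 / 2)
        assert res.genome_D == pytest.approx(0.0, abs=1e-12)


class TestGenomicDistance:
    @pytest.mark.parametrize(
        "pi1,pi2,pi12,expected",
        [
            (0.003, 0.003, 0.0015, 0.0),  # clone algebra: pi12 = h/2
            (0.003, 0.003, 0.003, 0.5),  # unrelated panmictic anchor
            (0.002, 0.002, 0.004, 0.75),
        ],
    )
    def test_anchor_values(self, pi1, pi2, pi12, expected):
        d = 1 - (pi1 + pi2) / (4 * pi12)
        assert d == pytest.approx(expected)

    def test_symmetry(self, small_cohort):
        matrix, _ = small_cohort
        frame = make_windows(matrix, "bp_span", 10**6)
        d_ab = pair_pi(matrix, "RK1", "MA1", frame).genome_D
        d_ba = pair_pi(matrix, "MA1", "RK1", frame).genome_D
        assert d_ab == pytest.approx(d_ba)

    def test_undefined_when_pi12_zero(self):
        m = matrix_from_genotypes([[0, 0], [0, 0]])
        frame = make_windows(m, "bp_span", 10**6)
        res = pair_pi(m, 0, 1, frame)
        assert np.isnan(res.genome_D)
        assert not res.table["defined"].iloc[0]

    def test_species_distance_above_half(self, small_cohort):
        """Founders of two differentiated species sit at D > 0.5."""
        matrix, _ = small_cohort
        frame = make_windows(matrix, "bp_span", 10**6)
        assert pair_pi(matrix, "RK1", "PU1", frame).genome_D > 0.5

    def test_distance_monotone_in_drift(self):
        """D between two populations' founders grows with the drift F."""
        ds = []
        for f in (0.2, 0.5, 0.8):
            model = PopulationModel(
                populations=("A", "B"), drift={"A": f, "B": f},
                n_chromosomes=1, chrom_length=5_000_000,
                sites_per_chromosome=5_000,
            )
            from hybridscope.sim import Founder, PedigreeSpec, build_cohort

            mat, _ = build_cohort(
                model, PedigreeSpec([Founder("a", "A"), Founder("b", "B")]), seed=2
            )
            frame = make_windows(mat, "bp_span", 5_000_000)
            ds.append(pair_pi(mat, "a", "b", frame).genome_D)
        assert ds[0] < ds[1] < ds[2]


class TestHeterozygosity:
    def test_all_hom_is_zero(self):
        m = matrix_from_genotypes([[0, 2, 0, 2]])
        frame = make_windows(m, "bp_span", 10**6)
        assert heterozygosity_windows(m, 0, frame)["het"].iloc[0] == 0.0

    def test_fraction_of_callable(self):
        g = np.zeros((1, 1000), dtype=np.int8)
        g[0, :250] = 1
        m = matrix_from_genotypes(g)
        frame = make_windows(m, "callable_count", 1000)
        t = heterozygosity_windows(m, 0, frame)
        assert t["het"].iloc[0] == pytest.approx(0.25)

    def test_empty_window_flagged(self):
        m = matrix_from_genotypes([[MISSING, MISSING]])
        frame = make_windows(m, "bp_span", 10**6)
        t = heterozygosity_windows(m, 0, frame)
        assert not t["defined"].iloc[0] and np.isnan(t["het"].iloc[0])


class TestFst:
    def test_null_within_population(self, panel_cohort):
        """Two groups drawn from one population: Fst ~ 0."""
        _, matrix, _ = panel_cohort
        fst = fst_wc(matrix, ["MA1", "U1"], ["MA2", "U2"])
        assert fst == pytest.approx(0.0, abs=0.02)

    def test_forced_equal_frequencies_nonpositive_numerator(self):
        geno = np.array([[0, 1, 2, 1], [2, 1, 0, 1], [0, 1, 2, 1], [2, 1, 0, 1]])
        m = matrix_from_genotypes(geno)
        fst, comp = fst_wc(m, [0, 1], [2, 3], return_components=True)
        assert np.all(comp.loc[comp["used"], "a"] <= 1e-12)

    def test_against_independent_oracle(self, fst_pair_cohort):
        """Vectorized estimator vs the literal scalar WC transcription."""
        matrix, group_a, group_b = fst_pair_cohort
        fst = fst_wc(matrix, group_a, group_b)
        oracle = _scalar_wc(matrix, group_a, group_b)
        assert fst == pytest.approx(oracle, abs=1e-10)
        assert fst == pytest.approx(0.5, abs=0.05)

    def test_symmetry(self, fst_pair_cohort):
        matrix, group_a, group_b = fst_pair_cohort
        assert fst_wc(matrix, group_a, group_b) == pytest.approx(
            fst_wc(matrix, group_b, group_a)
        )

    def test_monomorphic_only_undefined(self):
        m = matrix_from_genotypes([[0, 0], [0, 0], [0, 0], [0, 0]])
        assert np.isnan(fst_wc(m, [0, 1], [2, 3]))


def _scalar_wc(matrix, group_a, group_b):
    """Independent, literal per-site transcription of the two-population
    Weir-Cockerham (1984) variance components."""
    ga = np.stack([matrix.genotype_vector(s) for s in group_a]).astype(float)
    gb = np.stack([matrix.genotype_vector(s) for s in group_b]).astype(float)
    num = den = 0.0
    for j in range(matrix.n_sites):
        a1 = ga[:, j][ga[:, j] != MISSING]
        a2 = gb[:, j][gb[:, j] != MISSING]
        n1, n2 = len(a1), len(a2)
        if n1 < 1 or n2 < 1 or n1 + n2 < 3:
            continue
        p1, p2 = a1.mean() / 2, a2.mean() / 2
        h1, h2 = (a1 == 1).mean(), (a2 == 1).mean()
        r = 2.0
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        if pbar <= 0 or pbar >= 1 or nc <= 0 or nbar <= 1:
            continue
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


@pytest.fixture(scope="module")
def fst_pair_cohort():
    """Two populations at F=0.5, five founders each (~1e5 sites)."""
    from hybridscope.sim import Founder, PedigreeSpec, build_cohort

    model = PopulationModel(
        populations=("A", "B"), drift={"A": 0.5, "B": 0.5},
        n_chromosomes=2, chrom_length=25_000_000, sites_per_chromosome=50_000,
    )
    entries = [Founder(f"a{i}", "A") for i in range(5)]
    entries += [Founder(f"b{i}", "B") for i in range(5)]
    matrix, _ = build_cohort(model, PedigreeSpec(entries), seed=21)
    return matrix, [f"a{i}" for i in range(5)], [f"b{i}" for i in range(5)]


class TestPseudoDiploid:
    def test_sum_of_haplotypes(self):
        m = matrix_from_genotypes([[0, 1, 2]])
        h1 = np.array([0, 1, 1], dtype=np.int8)
        h2 = np.array([1, 0, 1], dtype=np.int8)
        pm = pseudo_diploid(m, [(h1, h2)])
        assert list(pm.genotypes[0]) == [1, 1, 2]

    def test_self_pairing_is_homozygous(self):
        m = matrix_from_genotypes([[0, 1, 2, 1]])
        h = np.array([0, 1, 1, 0], dtype=np.int8)
        pm = pseudo_diploid(m, [(h, h)])
        assert set(pm.genotypes[0]) <= {0, 2}

    def test_unresolved_propagates_missing(self):
        m = matrix_from_genotypes([[0, 1]])
        h1 = np.array([0, MISSING], dtype=np.int8)
        h2 = np.array([1, 1], dtype=np.int8)
        pm = pseudo_diploid(m, [(h1, h2)])
        assert pm.genotypes[0, 1] == MISSING

    def test_length_mismatch_rejected(self):
        m = matrix_from_genotypes([[0, 1]])
        with pytest.raises(ValueError):
            pseudo_diploid(m, [(np.zeros(3, dtype=np.int8), np.zeros(2, dtype=np.int8))])

    def test_fst_recovery_from_extracted_haplotypes(self, fst_pair_cohort):
        """Pseudo-diploids built from each population's haplotypes recover the
        founder-set Fst."""
        matrix, group_a, group_b = fst_pair_cohort
        direct = fst_wc(matrix, group_a, group_b)

        def extract(samples):
            # trivially "phase" HWE founders: hom sites split evenly, het
            # sites alternate — a haplotype sample with the right frequencies
            pairs = []
            rng = np.random.default_rng(1)
            for s in samples:
                g = matrix.genotype_vector(s)
                h1 = np.where(g == 2, 1, 0).astype(np.int8)
                h2 = h1.copy()
                het = g == 1
                flip = rng.random(het.sum()) < 0.5
                h1[np.flatnonzero(het)[flip]] = 1
                h2[np.flatnonzero(het)[~flip]] = 1
                pairs.append((h1, h2))
            return pairs

        pa = pseudo_diploid(matrix, extract(group_a),
                            [f"pa{i}" for i in range(len(group_a))])
        pb = pseudo_diploid(matrix, extract(group_b),
                            [f"pb{i}" for i in range(len(group_b))])
        merged = VariantMatrix(
            matrix.sites.reset_index(drop=True),
            np.vstack([pa.genotypes, pb.genotypes]),
            pd.concat([pa.samples, pb.samples], ignore_index=True),
        )
        redone = fst_wc(merged, pa.sample_ids, pb.sample_ids)
        assert redone == pytest.approx(direct, abs=0.05)


class TestFoldedAFS:
    def test_singleton_binning(self):
        geno = np.array([[1], [1], [1], [1]])
        m = matrix_from_genotypes(geno)
        afs = folded_afs(m, [0, 1, 2, 3])
        assert afs.counts[4] == 1  # alt count 4 of 8 -> folded bin 4

    def test_monomorphic_in_bin_zero(self):
        geno = np.zeros((4, 3), dtype=np.int8)
        m = matrix_from_genotypes(geno)
        afs = folded_afs(m, [0, 1, 2, 3])
        assert afs.counts[0] == 3

    def test_missing_and_excluded_sites_dropped(self):
        geno = np.array([[1, 0, 1], [1, MISSING, 1]])
        m = matrix_from_genotypes(geno, length=300)
        afs = folded_afs(m, [0, 1], exclude_intervals=[("chr1", 0, int(m.sites["pos"][0]))])
        assert afs.n_sites == 1

    def test_all_excluded_raises(self):
        m = matrix_from_genotypes([[0], [0]])
        with pytest.raises(ValueError):
            folded_afs(m, [0, 1], exclude_intervals=[("chr1", 0, 10**6)])

    def test_panmictic_spectrum_matches_sampling_oracle(self, panel_cohort):
        """Spectrum of 8 simulated panmictic diploids vs direct binomial
        sampling from the same population frequencies (independent oracle)."""
        model, matrix, truth = panel_cohort
        samples = ["MA1", "MA2", "MA3", "U1", "U2"]
        afs = folded_afs(matrix, samples)
        n_hap = afs.n_hap
        rng = np.random.default_rng(17)
        p = np.concatenate(truth.frequencies.freqs["MA"])
        alt = rng.binomial(n_hap, p)
        minor = np.minimum(alt, n_hap - alt)
        oracle = np.bincount(minor, minlength=n_hap // 2 + 1)
        obs = afs.normalized()
        exp = oracle / oracle.sum()
        assert np.abs(obs - exp).max() < 0.02
        # polymorphic part decays with minor-allele count
        assert obs[1] > obs[n_hap // 2]
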