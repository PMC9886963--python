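"""Gametes, founder diversity, pedigree kinship and ancestry tracking."""

import numpy as np
import pytest
from scipy import stats as sps

from rangesim.genetics import (
    Haplotype,
    PedigreeLog,
    _splice_positions,
    _splice_segments,
    ancestry_contributions,
    avg_sampled_relatedness,
    founder_mutation_sets,
    gamete,
    inject_founder_diversity,
    kinship,
    make_gamete,
    relatedness,
    relatedness_matrix,
    segments_tile,
    self_segments,
)
from rangesim.simcore import Individual, SimParams


class TestGamete:
    def test_no_recombination_no_mutation_copies_parent(self, rng):
        p = SimParams(mu=0.0, rec=0.0)
        a = Haplotype(np.array([1.0, 5.0, 9.0]))
        b = Haplotype(np.array([2.0, 6.0]))
        kids = {tuple(gamete(a, b, p, rng).muts) for _ in range(40)}
        assert kids == {(1.0, 5.0, 9.0), (2.0, 6.0)}

    def test_splice_positions_hand_case(self):
        a = np.array([1.0, 5.0, 9.0])
        b = np.array([2.0, 6.0])
        # [0, 4) from a, [4, G) from b
        assert _splice_positions(a, b, np.array([4.0]), 0).tolist() == [1.0, 6.0]
        # [0, 4) from b, [4, G) from a
        assert _splice_positions(a, b, np.array([4.0]), 1).tolist() == [2.0, 5.0, 9.0]

    def test_splice_segments_hand_case(self):
        G = 10.0
        la = (np.array([0.0]), np.array([11]))
        lb = (np.array([0.0, 3.0]), np.array([22, 33]))
        bps, labs = _splice_segments(la, lb, np.array([6.0]), 1, G)
        assert bps.tolist() == [0.0, 3.0, 6.0]
        assert labs.tolist() == [22, 33, 11]

    def test_per_gamete_count_distributions(self, rng):
        """Mutation and crossover counts match their Poisson laws (chi-square)."""
        p = SimParams(genome_length=10_000_000, mu=1e-6, rec=1e-7)
        a = Haplotype(np.empty(0), {0: (np.array([0.0]), np.array([0]))})
        b = Haplotype(np.empty(0), {0: (np.array([0.0]), np.array([1]))})
        n_mut, n_bp = [], []
        for _ in range(10_000):
            g = gamete(a, b, p, rng)
            n_mut.append(len(g.muts))
            bps, labs = g.layers[0]
            n_bp.append(len(labs) - 1)  # labels alternate 0/1, one per segment
        assert np.mean(n_mut) == pytest.approx(10.0, rel=0.05)
        assert np.mean(n_bp) == pytest.approx(1.0, rel=0.1)
        for counts, lam, kmax in ((n_mut, 10.0, 22), (n_bp, 1.0, 5)):
            obs = np.bincount(counts, minlength=kmax + 1)
            obs = np.concatenate([obs[:kmax], [obs[kmax:].sum()]])
            pk = sps.poisson.pmf(np.arange(kmax), lam)
            exp = np.concatenate([pk, [1 - pk.sum()]]) * len(counts)
            keep = exp > 1
            _, pval = sps.chisquare(obs[keep], exp[keep] * obs[keep].sum() / exp[keep].sum())
            assert pval > 0.01

    def test_desk_and_paper_profiles_share_per_gamete_means(self):
        desk = SimParams(genome_length=10_000_000, mu=1e-6, rec=1e-7)
        paper = SimParams(genome_length=1_000_000_000, mu=1e-8, rec=1e-9)
        for p in (desk, paper):
            assert p.genome_length * p.mu == pytest.approx(10.0)
            assert p.genome_length * p.rec == pytest.approx(1.0)

    def test_segment_tiling_conserved_through_gametes(self, rng):
        p = SimParams(genome_length=1_000_000, mu=1e-5, rec=2e-6)
        G = float(p.genome_length)
        a = Haplotype(np.empty(0), {0: self_segments(0, p)[0]})
        b = Haplotype(np.empty(0), {0: self_segments(0, p)[1]})
        for _ in range(60):
            c = gamete(a, b, p, rng)
            layer = c.layers[0]
            assert segments_tile(layer, G)
            lengths = np.diff(np.append(layer[0], G))
            assert lengths.sum() == pytest.approx(G)
            a, b = b, c

    def test_make_gamete_requires_genome(self, rng):
        ind = Individual(0, 1, 1)
        with pytest.raises(ValueError, match="genome"):
            make_gamete(ind, SimParams(), rng)


class TestFounderDiversity:
    def test_zero_theta_identical_haplotypes(self, rng):
        sets = founder_mutation_sets(10, 0.0, 1e6, rng)
        assert all(len(s) == 0 for s in sets)

    def test_single_shared_difference(self):
        # 2 founders differing at one site -> pairwise pi = 1/G
        from rangesim.popgen_stats import pairwise_divergence

        g1 = [(np.array([100.0]), np.array([100.0]))]
        g2 = [(np.empty(0), np.empty(0))]
        assert pairwise_divergence(g1, g2, 1e6) == pytest.approx(1 / 1e6)

    def test_target_theta_recovered(self, rng):
        # 50 diploid founders at theta 1e-3: sample pi within 10%
        G = 1e6
        sets = founder_mutation_sets(100, 1e-3, G, rng)
        diffs = [
            np.setxor1d(sets[a], sets[b], assume_unique=True).size
            for a in range(0, 100, 3)
            for b in range(a + 1, 100, 7)
        ]
        assert np.mean(diffs) / G == pytest.approx(1e-3, rel=0.10)

    def test_inject_assigns_genomes_to_individuals(self, rng):
        p = SimParams(genome_length=1_000_000)
        inds = [Individual(i, 1.0, 1.0) for i in range(6)]
        out = inject_founder_diversity(inds, 1e-3, p, rng)
        for ind in out:
            assert ind.genome is not None
            for hap in ind.genome:
                assert segments_tile(hap.layers[0], p.genome_length)

    def test_negative_theta_rejected(self, rng):
        with pytest.raises(ValueError):
            founder_mutation_sets(10, -1e-3, 1e6, rng)


def _random_pedigree(rng, n_founders=6, n_generations=6, per_gen=8):
    ped = PedigreeLog()
    gens = [[ped.add(-1, -1, 0, 0.0, 0.0) for _ in range(n_founders)]]
    for g in range(1, n_generations + 1):
        pool = [i for gen in gens for i in gen]
        kids = []
        for _ in range(per_gen):
            p1, p2 = rng.choice(pool, size=2, replace=False)
            kids.append(ped.add(int(p1), int(p2), g, 0.0, 0.0))
        gens.append(kids)
    return ped, gens


def _gene_drop_relatedness(ped, a, b, rng, n_drops=100_000):
    """Monte-Carlo r = 2 * P(random allele of a IBD random allele of b)."""
    n = len(ped)
    alleles = np.zeros((n, 2, n_drops), dtype=np.int32)
    for i in range(n):
        p1, p2 = ped.parents(i)
        if p1 < 0:
            alleles[i, 0] = 2 * i
            alleles[i, 1] = 2 * i + 1
        else:
            pick1 = rng.integers(0, 2, n_drops)
            pick2 = rng.integers(0, 2, n_drops)
            alleles[i, 0] = alleles[p1, pick1, np.arange(n_drops)]
            alleles[i, 1] = alleles[p2, pick2, np.arange(n_drops)]
    ibd = np.zeros(n_drops)
    for u in range(2):
        for v in range(2):
            ibd += alleles[a, u] == alleles[b, v]
    return float(2 * np.mean(ibd) / 4)


class TestKinship:
    def test_close_kin_identities(self):
        ped = PedigreeLog()
        f1 = ped.add(-1, -1, 0, 0, 0)
        f2 = ped.add(-1, -1, 0, 0, 0)
        f3 = ped.add(-1, -1, 0, 0, 0)
        kid1 = ped.add(f1, f2, 1, 0, 0)
        kid2 = ped.add(f1, f2, 1, 0, 0)  # full sib of kid1
        half = ped.add(f1, f3, 1, 0, 0)  # half sib
        grand = ped.add(kid1, f3, 2, 0, 0)
        assert relatedness(f1, kid1, ped) == pytest.approx(0.5)  # parent-offspring
        assert relatedness(kid1, kid2, ped) == pytest.approx(0.5)  # full sibs
        assert relatedness(kid1, half, ped) == pytest.approx(0.25)  # half sibs
        assert relatedness(f2, grand, ped) == pytest.approx(0.25)  # grandparent
        assert relatedness(f1, f2, ped) == 0.0
        assert relatedness(kid1, kid1, ped) == 1.0

    def test_unknown_id_rejected(self):
        ped = PedigreeLog()
        ped.add(-1, -1, 0, 0, 0)
        with pytest.raises(ValueError, match="unknown"):
            kinship(0, 5, ped)

    def test_depth_truncation_drops_distant_kin(self):
        ped = PedigreeLog()
        cur = ped.add(-1, -1, 0, 0, 0)
        other = ped.add(-1, -1, 0, 0, 0)
        lineage = [cur]
        for g in range(1, 6):
            mate = ped.add(-1, -1, g - 1, 0, 0)
            cur = ped.add(cur, mate, g, 0, 0)
            lineage.append(cur)
        # descendant and founder are related at depth 5 but not at depth 2
        assert relatedness(lineage[0], lineage[-1], ped, max_depth=10) > 0
        assert relatedness(lineage[0], lineage[-1], ped, max_depth=2) == 0.0
        assert relatedness(other, lineage[-1], ped) == 0.0

    def test_gene_dropping_oracle_on_random_pedigree(self, rng):
        ped, gens = _random_pedigree(rng)
        pairs = [(gens[-1][0], gens[-1][1]), (gens[-1][2], gens[-2][3]), (gens[-1][4], gens[-1][5])]
        for a, b in pairs:
            # gene dropping measures true IBD, so compare against the full
            # recursion (inbreeding included), not the diagonal-1 convention
            exact = 2 * kinship(a, b, ped, max_depth=10, include_inbreeding=True)
            n_drops = 100_000
            mc = _gene_drop_relatedness(ped, a, b, rng, n_drops)
            se = 2 * np.sqrt(max(exact / 2 * (1 - exact / 2), 1e-4) / n_drops) * 2
            assert mc == pytest.approx(exact, abs=max(3 * se, 0.01))


class TestAvgRelatedness:
    def test_unrelated_sample_is_zero(self):
        ped = PedigreeLog()
        ids = [ped.add(-1, -1, 0, 0, 0) for _ in range(5)]
        assert avg_sampled_relatedness(ids, ped) == 0.0

    def test_parent_offspring_pair(self):
        ped = PedigreeLog()
        f1 = ped.add(-1, -1, 0, 0, 0)
        f2 = ped.add(-1, -1, 0, 0, 0)
        kid = ped.add(f1, f2, 1, 0, 0)
        # matrix [[1, .5], [.5, 1]] -> r = 3, F_r = (3 - 2)/2
        assert avg_sampled_relatedness([f1, kid], ped) == pytest.approx(0.5)

    def test_small_sample_rejected(self):
        ped = PedigreeLog()
        i = ped.add(-1, -1, 0, 0, 0)
        with pytest.raises(ValueError, match="at least 2"):
            avg_sampled_relatedness([i], ped)

    def test_nonnegative_under_truncation(self, rng):
        ped, gens = _random_pedigree(rng)
        sample = [i for gen in gens[-2:] for i in gen]
        mat = relatedness_matrix(sample, ped)
        assert np.all(mat >= 0)
        assert np.all(np.diag(mat) == 1.0)
        assert avg_sampled_relatedness(sample, ped) >= 0


class TestAncestry:
    def test_self_slice_contributes_one(self):
        p = SimParams(genome_length=1000)
        segs = self_segments(7, p)
        haps = (Haplotype(np.empty(0), {5: segs[0]}), Haplotype(np.empty(0), {5: segs[1]}))
        contribs = ancestry_contributions(haps, 5, p.genome_length)
        assert contribs == {7: pytest.approx(1.0)}

    def test_dyadic_fractions_without_recombination(self, rng):
        p = SimParams(genome_length=1000, mu=0.0, rec=0.0)
        anchor = 0
        parents = []
        for i in range(4):
            sa, sb = self_segments(i, p)
            parents.append((Haplotype(np.empty(0), {anchor: sa}), Haplotype(np.empty(0), {anchor: sb})))
        kid = (
            gamete(*parents[0], p, rng),
            gamete(*parents[1], p, rng),
        )
        grandkid_hap = gamete(*kid, p, rng)
        other = gamete(*parents[2], p, rng)
        contribs = ancestry_contributions((grandkid_hap, other), anchor, p.genome_length)
        assert sum(contribs.values()) == pytest.approx(1.0)
        for frac in contribs.values():
            assert frac in (0.25, 0.5)

    def test_contributions_sum_to_one_with_recombination(self, rng):
        p = SimParams(genome_length=1_000_000, mu=1e-5, rec=5e-6)
        anchor = 0
        hap_pairs = []
        for i in range(6):
            sa, sb = self_segments(i, p)
            hap_pairs.append((Haplotype(np.empty(0), {anchor: sa}), Haplotype(np.empty(0), {anchor: sb})))
        for _ in range(5):
            nxt = []
            for j in range(6):
                pa, pb = hap_pairs[j], hap_pairs[(j + 1) % 6]
                nxt.append((gamete(*pa, p, rng), gamete(*pb, p, rng)))
            hap_pairs = nxt
        contribs = ancestry_contributions(hap_pairs[0], anchor, p.genome_length)
        assert sum(contribs.values()) == pytest.approx(1.0)

    def test_missing_anchor_rejected(self):
        p = SimParams(genome_length=1000)
        segs = self_segments(1, p)
        haps = (Haplotype(np.empty(0), {5: segs[0]}), Haplotype(np.empty(0), {5: segs[1]}))
        with pytest.raises(ValueError, match="anchor"):
            ancestry_contributions(haps, 3, p.genome_length)
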