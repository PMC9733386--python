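"""Motif discovery: sequence extraction, clustering against a brute-force
complete-linkage oracle, consensus construction, genomic enrichment against a
positional scan, the exact multinomial skew test against an independent
enumeration, and PFM similarity scoring."""

import itertools
import re

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from asqtl import motifs as mf
from asqtl.motifs import (VariantSequence, SequenceCluster, revcomp,
                          select_variants_for_motifs, extract_sequences,
                          cluster_sequences, build_consensus, genomic_enrichment,
                          allele_skew_test, summarize_skew, multinomial_llr,
                          pfm_similarity_score, pfm_similarity, ConsensusMotif,
                          read_jaspar_pfms, write_jaspar_pfms)


def _vs(seq, vid="v", orient="forward", pos_allele="A", ref_allele="A"):
    return VariantSequence(vid, seq, orient, pos_allele, ref_allele)


def _random_seq(rng, n=21):
    return "".join(rng.choice(list("ACGT"), n))


class TestSelectVariants:
    def _asb(self, mark, p, pos, fid="p1"):
        return pd.DataFrame([{"mark": mark, "feature_id": fid, "dsnp_id": "s1",
                              "pos": pos, "test1_p": p, "slope_sign": 1}])

    PEAKS = pd.DataFrame([{"feature_id": "p1", "chrom": "chr1",
                           "start": 100, "end": 200, "kind": "peak"}])

    def test_threshold_and_in_peak(self):
        kept = select_variants_for_motifs(self._asb("h3k4me1", 5e-9, 150),
                                          None, peaks=self.PEAKS)
        assert len(kept) == 1
        dropped = select_variants_for_motifs(self._asb("h3k4me1", 5e-8, 150),
                                             None, peaks=self.PEAKS)
        assert dropped.empty

    def test_outside_peak_dropped_except_acetylation(self):
        out = select_variants_for_motifs(self._asb("h3k4me3", 1e-9, 999),
                                         None, peaks=self.PEAKS)
        assert out.empty
        kept = select_variants_for_motifs(self._asb("h3k27ac", 1e-7, 999),
                                          None, peaks=self.PEAKS)
        assert len(kept) == 1

    def test_ase_tss_window(self):
        exons = pd.DataFrame([{"feature_id": "e1", "chrom": "chr1",
                               "start": 50_000, "end": 51_000, "kind": "exon"}])
        near = pd.DataFrame([{"feature_id": "e1", "dsnp_id": "s1",
                              "pos": 58_000, "test1_p": 1e-16, "slope_sign": 1}])
        far = near.assign(pos=62_001)
        assert len(select_variants_for_motifs(None, near, exons=exons)) == 1
        assert select_variants_for_motifs(None, far, exons=exons).empty

    def test_unknown_mark_rejected(self):
        with pytest.raises(ValueError, match="mark"):
            select_variants_for_motifs(self._asb("h3k9me3", 1e-9, 150),
                                       None, peaks=self.PEAKS)


class TestExtractSequences:
    SNPS = pd.DataFrame([
        {"snp_id": "s1", "chrom": "chr1", "pos": 50, "ref": "A", "alt": "G"},
        {"snp_id": "s2", "chrom": "chr1", "pos": 5, "ref": "C", "alt": "T"},
    ])

    def _variants(self, ids, sign=1):
        return pd.DataFrame({"dsnp_id": ids, "slope_sign": sign})

    def test_two_entries_per_variant_and_involution(self, rng):
        genome = {"chr1": _random_seq(rng, 200)}
        seqs, log = extract_sequences(self._variants(["s1"]), genome, self.SNPS)
        assert len(seqs) == 2 and log.empty
        fwd, rev = seqs
        assert len(fwd.seq) == 21
        assert revcomp(rev.seq) == fwd.seq
        assert fwd.seq[10] == genome["chr1"][50]

    def test_contig_end_skipped(self, rng):
        genome = {"chr1": _random_seq(rng, 200)}
        seqs, log = extract_sequences(self._variants(["s2"]), genome, self.SNPS)
        assert not seqs
        assert log.iloc[0]["reason"] == "contig-end"

    def test_n_in_flank_skipped(self):
        genome = {"chr1": "A" * 45 + "N" + "A" * 154}
        seqs, log = extract_sequences(self._variants(["s1"]), genome, self.SNPS)
        assert not seqs and log.iloc[0]["reason"] == "non-acgt"

    def test_positive_allele_follows_sign_and_orientation(self, rng):
        genome = {"chr1": _random_seq(rng, 200)}
        up, _ = extract_sequences(self._variants(["s1"], sign=1), genome, self.SNPS)
        down, _ = extract_sequences(self._variants(["s1"], sign=-1), genome, self.SNPS)
        assert up[0].positive_allele == "G" and down[0].positive_allele == "A"
        assert up[1].positive_allele == "C"  # complement on the revcomp entry
        assert up[0].reference_allele == "A" and up[1].reference_allele == "T"


def _lev(a, b):
    """DP Levenshtein, independent of the package's aligner."""
    dp = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        prev, dp[0] = dp[0], i
        for j, cb in enumerate(b, 1):
            prev, dp[j] = dp[j], min(dp[j] + 1, dp[j - 1] + 1,
                                     prev + (ca != cb))
    return dp[-1]


def _brute_complete_linkage_all(cores, cut, max_states=20_000):
    """All partitions reachable by exhaustive complete-linkage agglomeration
    with a distance cut, exploring every tie-consistent merge order (integer
    edit distances tie constantly, and the cut partition can depend on which
    minimal pair merges first)."""
    n = len(cores)
    dist = {(i, j): _lev(cores[i], cores[j])
            for i in range(n) for j in range(i + 1, n)}

    def cdist(a, b):
        return max(dist[(min(i, j), max(i, j))] for i in a for j in b)

    results = set()
    start = frozenset(frozenset([i]) for i in range(n))
    stack, seen = [start], {start}
    while stack:
        part = stack.pop()
        clusters = sorted(part, key=min)
        pairs = [(cdist(a, b), a, b) for i, a in enumerate(clusters)
                 for b in clusters[i + 1:]]
        mergeable = [p for p in pairs if p[0] <= cut]
        if not mergeable:
            results.add(part)
            continue
        dmin = min(p[0] for p in mergeable)
        for d, a, b in mergeable:
            if d != dmin:
                continue
            nxt = frozenset((part - {a, b}) | {a | b})
            if nxt not in seen and len(seen) < max_states:
                seen.add(nxt)
                stack.append(nxt)
    return results


class TestClustering:
    def test_identical_sequences_one_cluster(self, rng):
        seqs = [_vs("ACGTACGTACGTACGTACGTA") for _ in range(12)]
        out = cluster_sequences(seqs)
        assert len(out) == 1 and out[0].size == 12

    def test_distant_cores_never_co_clustered(self):
        a = _vs("AAAAAA" + "AAAAAAAAA" + "AAAAAA")
        b = _vs("AAAAAA" + "CCCCAAAAA" + "AAAAAA")  # core distance 4
        out = cluster_sequences([a] * 6 + [b] * 6, min_size=1)
        groups = [frozenset(id(m) for m in c.members) for c in out]
        ids_a = {id(s) for s in [a] * 6}
        for g in groups:
            assert not ({id(a)} <= g and {id(b)} <= g)
        # verify the cut criterion exhaustively: intra-cluster core distances <= 3
        import edlib
        for c in out:
            for x, y in itertools.combinations(c.members, 2):
                d = edlib.align(x.central(), y.central(), task="distance")["editDistance"]
                assert d <= 3

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 16))
        # mixture of one seeded family plus random cores to get mergers
        base = _random_seq(rng, 21)
        seqs = []
        for i in range(n):
            s = list(base)
            for _ in range(int(rng.integers(0, 4))):
                s[int(rng.integers(6, 15))] = rng.choice(list("ACGT"))
            if rng.random() < 0.4:
                s = list(_random_seq(rng, 21))
            seqs.append(_vs("".join(s), vid=f"v{i}"))
        ours = cluster_sequences(seqs, min_size=1)
        got = frozenset(frozenset(seqs.index(m) for m in c.members) for c in ours)
        valid = _brute_complete_linkage_all([s.central() for s in seqs], 3)
        assert got in valid

    def test_minimum_cluster_size_enforced(self, rng):
        seqs = [_vs(_random_seq(rng)) for _ in range(9)]
        assert cluster_sequences(seqs, min_size=10) == []

    def test_pfm_columns_sum_to_cluster_size(self, rng):
        seqs = [_vs("ACGTACGTACGTACGTACGTA") for _ in range(11)]
        pfm = SequenceCluster(members=seqs).pfm()
        assert (pfm.sum(axis=0) == 11).all()


class TestConsensus:
    def _pfm_from_freqs(self, cols, n=100):
        """cols: list of dicts base->freq."""
        arr = np.zeros((4, len(cols)))
        for j, col in enumerate(cols):
            for b, f in col.items():
                arr["ACGT".index(b), j] = round(f * n)
        return arr

    def test_worked_column_example(self):
        # A=0.4, C=0.3, G=0.2, T=0.1 at threshold 0.85 -> "[ACG]"
        conserved = {"A": 1.0}
        pfm = self._pfm_from_freqs([conserved,
                                    {"A": 0.4, "C": 0.3, "G": 0.2, "T": 0.1},
                                    conserved])
        cons = build_consensus(pfm)
        assert cons.regex == "A[ACG]A"
        assert cons.iupac == "AVA"

    def test_single_base_unbracketed(self):
        pfm = self._pfm_from_freqs([{"A": 1.0}])
        assert build_consensus(pfm).regex == "A"

    def test_strict_exceedance_boundary(self):
        # 0.86 > 0.85 stops at one base; 0.85 is not strictly above, so the
        # next base joins the class
        just_over = self._pfm_from_freqs([{"A": 0.86, "C": 0.14}], n=50)
        assert build_consensus(just_over).regex == "A"
        at_threshold = self._pfm_from_freqs([{"A": 0.85, "C": 0.15}], n=20)
        assert build_consensus(at_threshold).regex == "[AC]"

    def test_uninformative_flanks_trimmed(self):
        flat = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
        pfm = self._pfm_from_freqs([flat, {"A": 1.0}, {"C": 1.0}, flat], n=40)
        cons = build_consensus(pfm)
        assert (cons.start, cons.end) == (1, 3)
        assert cons.regex == "AC"

    def test_literal_entropy_trim_switch(self):
        flat = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
        pfm = self._pfm_from_freqs([{"A": 1.0}, flat, {"C": 1.0}], n=40)
        lit = build_consensus(pfm, literal_entropy_trim=True)
        # the literal reading trims the conserved flanks instead
        assert lit.regex.startswith("[") or lit.regex == "N"

    def test_all_trimmed_errors(self):
        flat = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
        with pytest.raises(ValueError, match="trimmed"):
            build_consensus(self._pfm_from_freqs([flat, flat], n=40))

    def test_tie_break_fixed_base_order(self):
        pfm = self._pfm_from_freqs([{"A": 0.45, "T": 0.45, "C": 0.05, "G": 0.05}], n=20)
        assert build_consensus(pfm).regex == "[AT]"


class TestGenomicEnrichment:
    def test_all_a_genome(self):
        motif = ConsensusMotif(0, 1, "W", "[AT]", ["AT"])
        enr = genomic_enrichment(motif, {"c": "A" * 1000},
                                 base_freqs=(0.25, 0.25, 0.25, 0.25))
        assert enr.observed == 1000
        assert enr.expected == pytest.approx(500.0)
        assert enr.enrichment == pytest.approx(2.0)

    def test_tiled_exact_motif(self):
        motif = ConsensusMotif(0, 4, "ACGT", "ACGT", ["A", "C", "G", "T"])
        enr = genomic_enrichment(motif, {"c": "ACGT" * 100},
                                 base_freqs=(0.25, 0.25, 0.25, 0.25))
        assert enr.observed == 100
        assert enr.expected == pytest.approx(400 * 0.25 ** 4)
        assert enr.enrichment == pytest.approx(64.0)

    def test_matches_positional_brute_force(self, rng):
        # non-overlapping forward scan oracle on a 10^5 bp genome
        genome = {"c1": _random_seq(rng, 60_000), "c2": _random_seq(rng, 40_000)}
        motif = ConsensusMotif(0, 4, "AVGT", "A[ACG]GT", ["A", "ACG", "G", "T"])
        enr = genomic_enrichment(motif, genome)
        pat = re.compile(motif.regex)
        count = 0
        for seq in genome.values():
            i = 0
            while i <= len(seq) - 4:
                if pat.match(seq, i) and pat.match(seq, i).start() == i:
                    count += 1
                    i += 4
                else:
                    i += 1
        assert enr.observed == count

    def test_null_calibration(self, rng):
        base_freqs = (0.291, 0.209, 0.209, 0.291)
        genome = {"c": "".join(rng.choice(list("ACGT"), 1_000_000,
                                          p=base_freqs))}
        motif = ConsensusMotif(0, 6, "ACGTAC", "ACGTAC",
                               ["A", "C", "G", "T", "A", "C"])
        enr = genomic_enrichment(motif, genome, base_freqs=base_freqs)
        sd = np.sqrt(enr.expected)
        assert abs(enr.observed - enr.expected) < 3 * sd


class TestSkewTest:
    def test_uniform_counts(self):
        res = allele_skew_test(list("ACGT") * 5)
        assert res.llr == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_single_base_exact(self):
        # 10 identical alleles: LLR = 20 ln 4; only the 4 monomorphic
        # outcomes reach it, p = 4 * 0.25^10
        res = allele_skew_test(["A"] * 10)
        assert res.llr == pytest.approx(20 * np.log(4), rel=1e-12)
        assert res.p == pytest.approx(4 * 0.25 ** 10, rel=1e-9)
        assert res.method == "exact"

    def test_exact_matches_independent_enumeration(self, rng):
        # oracle: scipy multinomial pmf summed over all compositions
        from scipy.stats import multinomial
        for n in (6, 9, 12):
            alleles = list(rng.choice(list("ACGT"), n, p=[0.6, 0.2, 0.1, 0.1]))
            res = allele_skew_test(alleles)
            obs = multinomial_llr([alleles.count(b) for b in "ACGT"])
            p = 0.0
            for c in itertools.product(range(n + 1), repeat=3):
                if sum(c) > n:
                    continue
                comp = (*c, n - sum(c))
                if multinomial_llr(comp) >= obs - 1e-9:
                    p += multinomial.pmf(comp, n, [0.25] * 4)
            assert res.p == pytest.approx(p, rel=1e-9)

    def test_monte_carlo_agrees_with_exact(self):
        alleles = ["A"] * 8 + ["C"] * 4 + ["G"] * 3
        exact = allele_skew_test(alleles, exact_max_n=20)
        mc = allele_skew_test(alleles, exact_max_n=1, n_draws=100_000, seed=3)
        assert mc.method == "monte-carlo"
        se = np.sqrt(exact.p * (1 - exact.p) / 100_000)
        assert abs(mc.p - exact.p) <= 3 * se + 1e-9

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            allele_skew_test([])


class TestSummarizeSkew:
    def _cluster(self, pos_alleles, rng):
        members = [_vs(_random_seq(rng), pos_allele=a, ref_allele=r)
                   for a, r in zip(pos_alleles,
                                   rng.choice(list("ACGT"), len(pos_alleles)))]
        return SequenceCluster(members=members)

    def test_conserved_positive_allele_detected(self, rng):
        clusters = []
        for _ in range(30):
            alleles = ["G"] * 14 + [rng.choice(list("ACGT")) for _ in range(2)]
            clusters.append(self._cluster(alleles, rng))
        out = summarize_skew(clusters)
        assert out.iloc[0]["positive_significant_pct"] > 90
        assert out.iloc[0]["reference_significant_pct"] < 30

    def test_empty_cluster_list(self):
        out = summarize_skew([])
        assert out.iloc[0]["n_clusters"] == 0
        assert out.iloc[0]["positive_significant_pct"] == 0.0


class TestPfmSimilarity:
    def test_identical_scores_100(self, rng):
        pfm = rng.integers(1, 30, size=(4, 8)).astype(float)
        assert pfm_similarity_score(pfm, pfm) == pytest.approx(100.0)

    def test_disjoint_single_column_zero(self):
        q = np.array([[1.0], [0], [0], [0]])
        t = np.array([[0.0], [0], [0], [1.0]])
        assert pfm_similarity_score(q, t) == pytest.approx(0.0)

    def test_half_overlap_scores_50(self):
        q = np.array([[0.5], [0.5], [0], [0]])
        t = np.array([[1.0], [0], [0], [0]])
        assert pfm_similarity_score(q, t) == pytest.approx(50.0)

    def test_best_offset_found(self):
        core = np.eye(4)[:, :4] * 10  # ACGT diagonal counts
        target = np.hstack([np.full((4, 3), 2.5), core, np.full((4, 3), 2.5)])
        assert pfm_similarity_score(core, target) == pytest.approx(100.0)

    def test_database_matching_threshold(self, tmp_path, rng):
        q = rng.integers(1, 20, size=(4, 6)).astype(float)
        other = rng.integers(1, 20, size=(4, 6)).astype(float)
        db = [("M1", "exact", q.copy(), "CORE"), ("M2", "other", other, "POLII")]
        hits = pfm_similarity("query", q, db, min_rel_score=90.0)
        assert hits and hits[0].database_id == "M1"
        assert all(h.rel_score > 90 for h in hits)

    def test_jaspar_round_trip(self, tmp_path):
        pfms = {"MA0001.1": np.array([[10, 0, 3], [0, 10, 3], [0, 0, 2], [0, 0, 2]],
                                     dtype=float)}
        path = tmp_path / "db.jaspar"
        write_jaspar_pfms(path, pfms)
        back = read_jaspar_pfms(path)
        assert back[0][0] == "MA0001.1"
        assert np.allclose(back[0][2], pfms["MA0001.1"])


class TestPlantedRecovery:
    def test_planted_cluster_consensus_and_enrichment(self):
        # 30 variants carrying a planted 9-mer (up to one mismatch) among 100
        # background variants: the planted cluster is recovered, its
        # consensus matches the plant, and the motif is genomically enriched
        rng = np.random.default_rng(99)
        plant = "TGACTCAGT"
        seqs = []
        for i in range(30):
            core = list(plant)
            if i % 3 == 0:  # every third instance carries one mismatch
                j = int(rng.integers(0, 9))
                core[j] = rng.choice([b for b in "ACGT" if b != core[j]])
            flank_l = _random_seq(rng, 6)
            flank_r = _random_seq(rng, 6)
            seqs.append(_vs(flank_l + "".join(core) + flank_r, vid=f"plant{i}"))
        for i in range(100):
            seqs.append(_vs(_random_seq(rng, 21), vid=f"bg{i}"))
        clusters = cluster_sequences(seqs)
        planted_ids = {f"plant{i}" for i in range(30)}
        best = max(clusters,
                   key=lambda c: sum(m.variant_id in planted_ids for m in c.members))
        recovered = sum(m.variant_id in planted_ids for m in best.members)
        assert recovered >= 25
        cons = build_consensus(best.pfm())
        # flank columns can survive trimming by sampling noise, so judge
        # fidelity on the planted columns (6..14) of the consensus span
        lo, hi = max(cons.start, 6), min(cons.end, 15)
        assert hi - lo >= 7  # most of the plant is retained
        central = "".join(c if len(c) == 1 else f"[{c}]"
                          for c in cons.columns[lo - cons.start:hi - cons.start])
        assert re.fullmatch(central, plant[lo - 6:hi - 6])
        # genome with the plant at 5x its background expectation
        genome = {"c": _random_seq(rng, 200_000)}
        enr0 = genomic_enrichment(ConsensusMotif(0, 9, "", plant, list(plant)),
                                  genome, base_freqs=(0.25,) * 4)
        n_insert = max(1, int(np.ceil(5 * enr0.expected)) - enr0.observed)
        g = list(genome["c"])
        step = len(g) // (n_insert + 1)
        for k in range(n_insert):
            pos = (k + 1) * step
            g[pos:pos + 9] = plant
        enr = genomic_enrichment(ConsensusMotif(0, 9, "", plant, list(plant)),
                                 {"c": "".join(g)}, base_freqs=(0.25,) * 4)
        assert enr.enrichment > 2.0
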