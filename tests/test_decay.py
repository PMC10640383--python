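import numpy as np
import pytest

from conftest import random_dna
from oracles import sw_oracle

from gevescan import synth
from gevescan.decay import (
    PseudogeneCluster,
    align_protein_local,
    classify_cluster,
    cluster_fragmented_orfs,
    evalue_from_score,
    repeat_density,
    summarize_gene_traces,
    taxonomy_breakdown,
    translated_search,
)
from gevescan.intervals import Interval
from gevescan.orfs import BestHit, OrfRecord

AA = list("ACDEFGHIKLMNPQRSTVWY")


def _orf(start, end, subject, s_start, s_end, strand="+", frame=0, contig="c"):
    return OrfRecord(
        Interval(contig, start, end, strand),
        frame,
        (end - start + 1) // 3,
        best_hit=BestHit(subject, s_start, s_end, 1e-20, "virus"),
    )


class TestClustering:
    def test_collinear_fragments_merge(self):
        a = _orf(100, 399, "P", 1, 100)
        b = _orf(500, 740, "P", 120, 200)
        clusters = cluster_fragmented_orfs([a, b])
        assert len(clusters) == 1
        assert clusters[0].members == [a, b]

    def test_opposite_strands_no_cluster(self):
        a = _orf(100, 399, "P", 1, 100, strand="+")
        b = _orf(500, 740, "P", 120, 200, strand="-")
        assert cluster_fragmented_orfs([a, b]) == []

    def test_different_subjects_no_cluster(self):
        a = _orf(100, 399, "P", 1, 100)
        b = _orf(500, 740, "Q", 120, 200)
        assert cluster_fragmented_orfs([a, b]) == []

    def test_gap_limit(self):
        a = _orf(100, 399, "P", 1, 100)
        b = _orf(6000, 6299, "P", 120, 200)
        assert cluster_fragmented_orfs([a, b], max_gap=5000) == []
        assert len(cluster_fragmented_orfs([a, b], max_gap=6000)) == 1

    def test_nested_coverage_rejected(self):
        a = _orf(100, 399, "P", 1, 100)
        b = _orf(500, 740, "P", 20, 80)  # nested in a's coverage
        assert cluster_fragmented_orfs([a, b]) == []

    def test_minus_strand_collinearity_is_reversed(self):
        # translation order on '-' is descending start: coverage must
        # decrease along the genome
        a = _orf(100, 399, "P", 120, 200, strand="-")
        b = _orf(500, 740, "P", 1, 100, strand="-")
        assert len(cluster_fragmented_orfs([a, b])) == 1
        # and the '+'-style layout must be rejected on '-'
        c = _orf(100, 399, "P", 1, 100, strand="-")
        d = _orf(500, 740, "P", 120, 200, strand="-")
        assert cluster_fragmented_orfs([c, d]) == []

    def test_unsorted_input_rejected(self):
        a = _orf(500, 740, "P", 120, 200)
        b = _orf(100, 399, "P", 1, 100)
        with pytest.raises(ValueError):
            cluster_fragmented_orfs([a, b])

    def test_clusters_partition_members(self):
        orfs = [
            _orf(100, 399, "P", 1, 100),
            _orf(500, 740, "P", 120, 200),
            _orf(800, 1000, "Q", 1, 60),
            _orf(1100, 1300, "Q", 70, 130),
        ]
        clusters = cluster_fragmented_orfs(orfs)
        seen = [id(m) for c in clusters for m in c.members]
        assert len(seen) == len(set(seen)) == 4

    def test_singletons_are_not_clusters(self):
        assert cluster_fragmented_orfs([_orf(100, 399, "P", 1, 100)]) == []


class TestClassification:
    def _sequence_with_gap(self, gap: str, left=(100, 399), right=None):
        right = right or (400 + len(gap), 699 + len(gap))
        seq = list(random_dna(np.random.default_rng(0), 1000))
        seq[left[1] : left[1] + len(gap)] = list(gap)
        return "".join(seq), left, (left[1] + len(gap) + 1, left[1] + len(gap) + 300)

    def test_canonical_splice_contiguous_coverage(self):
        gap = "GT" + "A" * 50 + "AG"
        seq, (ls, le), (rs, re) = self._sequence_with_gap(gap)
        a = _orf(ls, le, "P", 1, 100)
        b = _orf(rs, re, "P", 101, 200)
        cluster = classify_cluster(PseudogeneCluster([a, b], "P"), seq)
        assert cluster.classification == "intron_candidate"
        assert cluster.disruptions == []

    def test_frame_break_is_pseudogene_with_frameshift(self):
        gap = "C"  # 1-bp gap, no splice motif, shifts the frame
        seq, (ls, le), (rs, re) = self._sequence_with_gap(gap)
        a = _orf(ls, le, "P", 1, 100)
        b = _orf(rs, re, "P", 101, 200)
        cluster = classify_cluster(PseudogeneCluster([a, b], "P"), seq)
        assert cluster.classification == "pseudogene"
        assert cluster.disruptions == ["frameshift"]

    def test_inframe_stop_is_stop_gain(self):
        gap = "TAG"
        seq, (ls, le), (rs, re) = self._sequence_with_gap(gap)
        a = _orf(ls, le, "P", 1, 100)
        b = _orf(rs, re, "P", 102, 200)
        cluster = classify_cluster(PseudogeneCluster([a, b], "P"), seq)
        assert cluster.classification == "pseudogene"
        assert cluster.disruptions == ["stop_gain"]

    def test_noncontiguous_coverage_breaks_intron_call(self):
        gap = "GT" + "A" * 50 + "AG"
        seq, (ls, le), (rs, re) = self._sequence_with_gap(gap)
        a = _orf(ls, le, "P", 1, 100)
        b = _orf(rs, re, "P", 150, 250)  # 49-residue coverage gap
        cluster = classify_cluster(PseudogeneCluster([a, b], "P"), seq)
        assert cluster.classification == "pseudogene"

    def test_minus_strand_splice_checked_on_coding_strand(self):
        # genome carries revcomp(GT..AG) = CT..AC between '-' strand members
        gap = "CT" + "T" * 50 + "AC"
        seq, (ls, le), (rs, re) = self._sequence_with_gap(gap)
        # on '-', translation order is right member first
        a = _orf(ls, le, "P", 101, 200, strand="-")
        b = _orf(rs, re, "P", 1, 100, strand="-")
        cluster = classify_cluster(PseudogeneCluster([a, b], "P"), seq)
        assert cluster.classification == "intron_candidate"

    def test_deterministic(self):
        gap = "TAG"
        seq, (ls, le), (rs, re) = self._sequence_with_gap(gap)
        a = _orf(ls, le, "P", 1, 100)
        b = _orf(rs, re, "P", 102, 200)
        c1 = classify_cluster(PseudogeneCluster([a, b], "P"), seq)
        c2 = classify_cluster(PseudogeneCluster([a, b], "P"), seq)
        assert (c1.classification, c1.disruptions) == (c2.classification, c2.disruptions)


class TestDecayRecovery:
    """Generator-truth oracle: cluster+classify against simulated labels."""

    def _run_seed(self, seed):
        sim_insert = synth.InsertModel(length=150_000, n_genes=50)
        seq, genes, _ = synth.generate_viral_insert(sim_insert, synth.DecayModel(), seed=seed)
        truth = synth.SyntheticTruth(
            insert_interval=Interval("chr1", 1, len(seq)),
            gene_models=genes,
            decay_events=[],
        )
        records = synth.truth_orf_records(truth, len(seq))
        clusters = [
            classify_cluster(c, seq) for c in cluster_fragmented_orfs(records)
        ]
        return genes, clusters

    def test_f1_and_accuracy(self):
        tp = fp = fn = correct = labeled = 0
        for seed in range(10):
            genes, clusters = self._run_seed(seed)
            decayed = {
                f"prot{i:05d}": g.status
                for i, g in enumerate(genes)
                if g.status != "intact"
            }
            called = {c.subject_id: c.classification for c in clusters}
            tp += len(set(called) & set(decayed))
            fp += len(set(called) - set(decayed))
            fn += len(set(decayed) - set(called))
            for subject, status in decayed.items():
                if subject in called:
                    labeled += 1
                    expected = (
                        "intron_candidate" if status == "intron_bearing" else "pseudogene"
                    )
                    correct += called[subject] == expected
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        f1 = 2 * precision * recall / (precision + recall)
        assert f1 >= 0.9
        assert labeled > 0 and correct / labeled >= 0.9


class TestTranslatedSearch:
    def _protein(self, rng, n):
        return "".join(rng.choice(AA, size=n))

    def test_planted_identity_is_best_hit(self, rng):
        target = self._protein(rng, 120)
        segment = target[30:90]  # 60 residues
        # reverse-translate with one fixed codon per residue
        codon = {
            "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
            "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
            "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
            "W": "TGG", "Y": "TAT",
        }
        query = "".join(codon[a] for a in segment)
        db = [("decoy%d" % i, self._protein(rng, 100)) for i in range(4)] + [("target", target)]
        hits = translated_search([("q1", query)], db, e_threshold=1e-5)
        assert "q1" in hits
        hit = hits["q1"]
        assert hit.subject_id == "target"
        assert hit.evalue < 1e-10
        assert (hit.subject_start, hit.subject_end) == (31, 90)

    def test_random_queries_no_hits_mostly(self):
        # empirical null: random 300-bp queries vs unrelated proteins
        hits_found = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            query = random_dna(rng, 300, gc=0.5)
            db = [(f"p{i}", self._protein(rng, 80)) for i in range(20)]
            hits = translated_search([("q", query)], db, e_threshold=1e-5)
            hits_found += bool(hits)
        assert hits_found / n_seeds <= 0.05

    @pytest.mark.parametrize("seed", range(4))
    def test_scores_match_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        q = self._protein(rng, 40)
        s = self._protein(rng, 60)
        score, _, _ = align_protein_local(q, s)
        assert score == sw_oracle(q, s)

    def test_evalue_monotone_in_score(self):
        evs = [evalue_from_score(s, 100, 10_000) for s in (20, 40, 60, 80)]
        assert evs == sorted(evs, reverse=True)

    def test_short_query_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            hits = translated_search([("tiny", "AC")], [("p", "MKV")])
        assert hits == {}

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            translated_search([("q", "ATGGCA")], [])


class TestTraceSummary:
    def test_one_decimal_percentages(self):
        queries = [f"q{i}" for i in range(1095)]
        s = summarize_gene_traces(queries, queries[:124], queries[:222])
        assert s.pct_db1 == 11.3
        assert s.pct_db2 == 20.3
        assert s.n_both == 124

    def test_disjoint_hit_sets(self):
        queries = ["a", "b", "c", "d"]
        s = summarize_gene_traces(queries, ["a"], ["b"])
        assert s.n_both == 0

    def test_hits_outside_queries_ignored(self):
        s = summarize_gene_traces(["a", "b"], ["a", "zzz"], [])
        assert s.n_db1 == 1


class TestRepeatDensity:
    REGION = Interval("c", 1, 10_000)

    def test_constructed_split(self):
        ann = [(Interval("c", 1, 5000), "repeat")]
        orfs = [_orf(6001, 6300, "P", 1, 100)]
        d = repeat_density(ann, self.REGION, orfs)
        assert d.total_fraction == 0.5
        assert d.coding_fraction == 0.0
        assert d.noncoding_fraction == 0.5

    def test_empty_annotation(self):
        d = repeat_density([], self.REGION, [])
        assert (d.total_fraction, d.coding_fraction, d.noncoding_fraction, d.te_fraction) == (
            0.0, 0.0, 0.0, 0.0,
        )

    def test_te_subset(self):
        ann = [(Interval("c", 1, 1000), "repeat"), (Interval("c", 2001, 2500), "TE:LTR")]
        d = repeat_density(ann, self.REGION, [])
        assert d.total_fraction == pytest.approx(0.15)
        assert d.te_fraction == pytest.approx(0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_component_additivity(self, seed):
        rng = np.random.default_rng(seed)
        ann = [
            (Interval("c", int(s), int(s) + int(l)), "repeat" if i % 3 else "TE:x")
            for i, (s, l) in enumerate(zip(rng.integers(1, 9000, 40), rng.integers(10, 900, 40)))
        ]
        orfs = [
            _orf(int(s), int(s) + int(l) // 3 * 3 + 2, f"P{i}", 1, 100)
            for i, (s, l) in enumerate(zip(rng.integers(1, 9000, 20), rng.integers(30, 600, 20)))
        ]
        d = repeat_density(ann, self.REGION, orfs)
        assert d.coding_fraction + d.noncoding_fraction == pytest.approx(d.total_fraction, abs=1e-9)


class TestTaxonomy:
    def _hits(self, euk, prok, vir):
        out = []
        for n, taxon in ((euk, "eukaryote"), (prok, "prokaryote"), (vir, "virus")):
            out += [BestHit(f"s{i}", 1, 10, 1e-9, taxon, f"{taxon};lineage") for i in range(n)]
        return out

    def test_reference_counts(self):
        coarse, lineages = taxonomy_breakdown(self._hits(108, 10, 25))
        assert coarse["eukaryote"] == 108
        assert coarse["prokaryote"] == 10
        assert coarse["virus"] == 25

    def test_empty(self):
        coarse, lineages = taxonomy_breakdown([])
        assert coarse == {"eukaryote": 0, "prokaryote": 0, "virus": 0}
        assert lineages == {}

    def test_order_invariance(self, rng):
        hits = self._hits(5, 3, 2)
        shuffled = list(hits)
        rng.shuffle(shuffled)
        assert taxonomy_breakdown(hits) == taxonomy_breakdown(shuffled)

    def test_unknown_label_warns(self):
        with pytest.warns(UserWarning):
            coarse, _ = taxonomy_breakdown([BestHit("s", 1, 2, 1e-9, "archaeon")])
        assert coarse["unclassified"] == 1
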