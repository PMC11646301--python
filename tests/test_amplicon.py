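"""Read merging, trimming, filtering, denoising, chimera/numt removal, mapping."""

import numpy as np
import pytest

import sedchiro as sc
from sedchiro import (
    CH_PRIMERS,
    ESV,
    QualityRead,
    Unique,
    denoise_d1,
    dereplicate,
    detect_chimeras,
    filter_numts,
    map_reads,
    merge_pairs,
    quality_filter,
    revcomp,
    trim_primers,
)
from sedchiro.amplicon import has_stop_codon, is_perfect_chimera

RNG = np.random.default_rng(77)


def random_dna(n, rng=RNG):
    return "".join(np.array(list("ACGT"))[rng.integers(4, size=n)])


def read(seq, q=40, read_id="r", sample="s"):
    return QualityRead(read_id, seq, np.full(len(seq), q), sample=sample)


def make_pair(template, read_len, q=40):
    r1 = read(template[:read_len], q)
    r2 = read(revcomp(template)[:read_len], q)
    return r1, r2


class TestMerge:
    def test_perfect_overlap_length(self):
        template = random_dna(140)
        r1, r2 = make_pair(template, 100)  # 60 nt overlap
        merged, why = merge_pairs(r1, r2)
        assert why is None
        assert len(merged.sequence) == 100 + 100 - 60
        assert merged.sequence == template

    def test_overlap_below_minimum_rejected(self):
        template = random_dna(160)
        r1, r2 = make_pair(template, 100)  # 40 nt overlap
        merged, why = merge_pairs(r1, r2)
        assert merged is None and why == "overlap_too_short"

    def test_too_many_differences_rejected(self):
        template = random_dna(140)
        r1, r2 = make_pair(template, 100)
        # inject 11 mismatches into r1's overlap region (positions 40..50)
        chars = list(r1.sequence)
        for i in range(40, 51):
            chars[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[i]]
        r1 = QualityRead("r", "".join(chars), r1.qualities, sample="s")
        merged, why = merge_pairs(r1, r2)
        assert merged is None and why == "too_many_diffs"

    def test_conflict_takes_higher_quality_base(self):
        template = random_dna(140)
        r1, r2 = make_pair(template, 100)
        chars = list(r1.sequence)
        pos = 70  # inside the overlap
        wrong = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[pos]]
        chars[pos] = wrong
        q1 = r1.qualities.copy()
        q1[pos] = 10  # r2's base (q40) must win
        r1 = QualityRead("r", "".join(chars), q1, sample="s")
        merged, _ = merge_pairs(r1, r2)
        assert merged.sequence == template
        assert merged.qualities[pos] == 30  # |40 - 10| at the conflict

    def test_agreement_takes_max_quality(self):
        template = random_dna(140)
        r1, r2 = make_pair(template, 100, q=30)
        q1 = r1.qualities.copy()
        q1[:] = 20
        r1 = QualityRead("r", r1.sequence, q1, sample="s")
        merged, _ = merge_pairs(r1, r2)
        # overlap region takes max(20, 30) = 30
        assert merged.qualities[50] == 30


class TestTrim:
    def setup_method(self):
        rng = np.random.default_rng(5)
        from sedchiro.refdb import IUPAC

        self.fwd = "".join(
            sorted(IUPAC[c])[rng.integers(len(IUPAC[c]))]
            for c in CH_PRIMERS.forward.bases
        )
        self.rev = "".join(
            sorted(IUPAC[c])[rng.integers(len(IUPAC[c]))]
            for c in CH_PRIMERS.reverse.bases
        )
        self.insert = random_dna(139, rng)

    def test_linked_anchored_trim_returns_insert(self):
        r = read(self.fwd + self.insert + revcomp(self.rev))
        out, why = trim_primers(r, CH_PRIMERS)
        assert why is None and out.sequence == self.insert

    def test_forward_at_offset_rejected(self):
        r = read("ACG" + self.fwd + self.insert + revcomp(self.rev))
        out, why = trim_primers(r, CH_PRIMERS)
        assert out is None and why == "no_forward_anchor"

    def test_missing_reverse_rejected(self):
        r = read(self.fwd + self.insert)
        out, why = trim_primers(r, CH_PRIMERS)
        assert out is None and why == "no_reverse"


class TestQualityFilter:
    def test_length_deviation_drops(self):
        keep, why = quality_filter(read(random_dna(194)), expected_len=205)
        assert not keep and why == "length_out_of_window"

    def test_expected_errors_closed_form(self):
        r = read(random_dna(200), q=40)
        assert r.expected_errors == pytest.approx(200 * 1e-4)
        keep, why = quality_filter(r, expected_len=200)
        assert keep

    def test_ee_at_or_above_one_drops(self):
        # 100 bases at Q20 -> EE = 1.0 exactly, which is >= 1
        r = read(random_dna(139), q=35)
        quals = r.qualities.copy()
        quals[:100] = 20
        r = QualityRead("r", r.sequence, quals, sample="s")
        assert r.expected_errors >= 1.0
        keep, why = quality_filter(r, expected_len=139)
        assert not keep and why == "expected_errors"

    def test_low_mean_q_drops(self):
        r = read(random_dna(139), q=29)
        keep, why = quality_filter(r, expected_len=139, max_ee=100.0)
        assert not keep and why == "low_mean_q"


class TestDereplicate:
    def test_sorted_by_abundance_then_sequence(self):
        reads = [read("AAA", read_id=f"r{i}") for i in range(3)]
        reads += [read("CCC", read_id=f"c{i}") for i in range(2)]
        uniques = dereplicate(reads)
        assert [(u.sequence, u.total) for u in uniques] == [("AAA", 3), ("CCC", 2)]

    def test_per_sample_abundances_add(self):
        reads = [read("AAA", sample="s1")] * 2 + [read("AAA", sample="s2")] * 5
        uniques = dereplicate(reads)
        assert uniques[0].abundance_by_sample == {"s1": 2, "s2": 5}
        assert uniques[0].total == 7

    def test_empty_input(self):
        assert dereplicate([]) == []


def levenshtein(a, b):
    """Plain DP oracle, independent of edlib."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def brute_force_components(seqs, d=1):
    """Connected components of the distance-<=d graph (union-find oracle)."""
    parent = list(range(len(seqs)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if levenshtein(seqs[i], seqs[j]) <= d:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(len(seqs)):
        groups.setdefault(find(i), []).append(i)
    return sorted(sorted(g) for g in groups.values())


class TestDenoise:
    def test_neighbor_absorbed_into_seed(self):
        a = random_dna(50)
        b = a[:-1] + ("A" if a[-1] != "A" else "C")
        esvs, membership = denoise_d1(
            [Unique(a, {"s": 100}), Unique(b, {"s": 5})], fastidious=False
        )
        assert len(esvs) == 1
        assert esvs[0].sequence == a and esvs[0].total_abundance == 105

    def test_distant_uniques_stay_separate(self):
        a = random_dna(50)
        chars = list(a)
        for i in (10, 20, 30):
            chars[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[i]]
        b = "".join(chars)
        esvs, _ = denoise_d1([Unique(a, {"s": 100}), Unique(b, {"s": 50})])
        assert len(esvs) == 2

    def test_chain_growth_links_distance_two_endpoints(self):
        a = random_dna(50)
        b = a[:10] + ("A" if a[10] != "A" else "C") + a[11:]
        c = b[:30] + ("A" if b[30] != "A" else "C") + b[31:]
        assert levenshtein(a, c) == 2
        esvs, _ = denoise_d1(
            [Unique(a, {"s": 100}), Unique(b, {"s": 5}), Unique(c, {"s": 2})],
            fastidious=False,
        )
        assert len(esvs) == 1 and esvs[0].total_abundance == 107

    def test_fastidious_grafts_small_cluster_at_distance_two(self):
        a = random_dna(60)
        chars = list(a)
        chars[5] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[5]]
        chars[40] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[40]]
        b = "".join(chars)
        uniques = [Unique(a, {"s": 100}), Unique(b, {"s": 2})]
        grafted, _ = denoise_d1(uniques, fastidious=True, boundary=3)
        assert len(grafted) == 1 and grafted[0].total_abundance == 102
        separate, _ = denoise_d1(uniques, fastidious=False)
        assert len(separate) == 2

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_connected_components_oracle(self, seed):
        rng = np.random.default_rng(seed)
        base = "".join(np.array(list("ACGT"))[rng.integers(4, size=30)])
        seqs = set()
        while len(seqs) < min(12, 3 + seed):
            s = list(base)
            for _ in range(rng.integers(0, 3)):
                p = rng.integers(len(s))
                s[p] = "ACGT"[rng.integers(4)]
            seqs.add("".join(s))
        seqs = sorted(seqs)
        uniques = [
            Unique(s, {"s": int(rng.integers(1, 100))}) for s in seqs
        ]
        esvs, membership = denoise_d1(uniques, fastidious=False)
        expected = brute_force_components(seqs)
        got = {}
        for u in uniques:
            got.setdefault(membership[u.sequence], []).append(seqs.index(u.sequence))
        got = sorted(sorted(g) for g in got.values())
        assert got == expected


class TestChimeras:
    def make_parents(self):
        a = random_dna(120)
        b = random_dna(120)
        return a, b

    def test_constructed_perfect_chimera_flagged(self):
        a, b = self.make_parents()
        chimera = a[:60] + b[60:]
        esvs = [
            ESV("p1", a, {"s": 100}),
            ESV("p2", b, {"s": 64}),
            ESV("q", chimera, {"s": 2}),
        ]
        retained, flagged = detect_chimeras(esvs)
        assert [e.esv_id for e in flagged] == ["q"]

    def test_insufficient_skew_not_flagged(self):
        a, b = self.make_parents()
        chimera = a[:60] + b[60:]
        esvs = [
            ESV("p1", a, {"s": 100}),
            ESV("p2", b, {"s": 64}),
            ESV("q", chimera, {"s": 10}),  # 64 < 16 * 10
        ]
        retained, flagged = detect_chimeras(esvs)
        assert flagged == []

    def test_unreconstructable_esv_not_flagged(self):
        a, b = self.make_parents()
        other = random_dna(120)
        esvs = [
            ESV("p1", a, {"s": 100}),
            ESV("p2", b, {"s": 64}),
            ESV("q", other, {"s": 1}),
        ]
        _, flagged = detect_chimeras(esvs)
        assert flagged == []

    def test_parents_never_flagged(self):
        a, b = self.make_parents()
        chimera = a[:60] + b[60:]
        esvs = [
            ESV("p1", a, {"s": 1000}),
            ESV("p2", b, {"s": 640}),
            ESV("q", chimera, {"s": 2}),
        ]
        retained, flagged = detect_chimeras(esvs)
        assert {e.esv_id for e in retained} == {"p1", "p2"}

    def test_crossover_must_be_internal(self):
        a, b = self.make_parents()
        assert not is_perfect_chimera(a, [a, b])


class TestNumts:
    def stop_free(self, n_codons=20, rng=None):
        rng = rng or np.random.default_rng(3)
        codons = []
        while len(codons) < n_codons:
            c = "".join(np.array(list("ACGT"))[rng.integers(4, size=3)])
            if c not in ("TAA", "TAG"):
                codons.append(c)
        return "".join(codons)

    def test_in_frame_taa_removed(self):
        seq = self.stop_free(10) + "TAA" + self.stop_free(10)
        retained, removed, reasons = filter_numts([ESV("e", seq, {"s": 1})])
        assert retained == [] and reasons["stop_codon"] == 1

    def test_aga_is_serine_not_stop_in_table5(self):
        seq = self.stop_free(10) + "AGA" + self.stop_free(10)
        retained, removed, _ = filter_numts([ESV("e", seq, {"s": 1})])
        assert len(retained) == 1

    def test_stop_free_retained(self):
        retained, removed, _ = filter_numts([ESV("e", self.stop_free(20), {"s": 1})])
        assert len(retained) == 1

    def test_frame_offset_respected(self):
        seq = "A" + self.stop_free(10) + "TAA" + self.stop_free(10)
        assert has_stop_codon(seq, frame_offset=1) is True
        # frame 0 reads across codon boundaries; may or may not hit a stop
        retained, removed, reasons = filter_numts(
            [ESV("e", seq, {"s": 1})], frame_offset=1
        )
        assert reasons.get("stop_codon") == 1

    def test_too_short_to_translate(self):
        retained, removed, reasons = filter_numts(
            [ESV("e", "AC", {"s": 1})], frame_offset=1
        )
        assert reasons["too_short_to_translate"] == 1


class TestMapReads:
    def setup_method(self):
        self.a = random_dna(80)
        self.b = random_dna(80)
        self.esvs = [
            ESV("esv_1", self.a, {"s1": 50}),
            ESV("esv_2", self.b, {"s1": 10}),
        ]

    def test_identical_read_assigned(self):
        table, unmapped = map_reads([read(self.a, sample="s1")], self.esvs)
        assert table.loc["esv_1", "s1"] == 1 and unmapped == 0

    def test_one_substitution_assigned(self):
        q = self.a[:-1] + ("A" if self.a[-1] != "A" else "C")
        table, unmapped = map_reads([read(q, sample="s1")], self.esvs)
        assert table.loc["esv_1", "s1"] == 1

    def test_two_differences_unmapped(self):
        chars = list(self.a)
        chars[0] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[0]]
        chars[40] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[40]]
        table, unmapped = map_reads([read("".join(chars), sample="s1")], self.esvs)
        assert unmapped == 1

    def test_tie_broken_toward_higher_abundance(self):
        # read at distance 1 from both ESVs
        a = "A" * 40
        b = "A" * 39 + "G"
        esvs = [ESV("big", a, {"s": 100}), ESV("small", b, {"s": 5})]
        q = "A" * 39 + "T"  # distance 1 from both
        table, _ = map_reads([read(q, sample="s")], esvs)
        assert table.loc["big", "s"] == 1
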