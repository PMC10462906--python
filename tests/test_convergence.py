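"""Common-epitope metrics, the 2-of-3 vote, and epitope grouping."""

import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcrepertoire.clones import Clone, group_clones
from gcrepertoire.convergence import (
    ConvergencePair,
    ParatopeProfile,
    abligity_score,
    categorize_pair,
    cdr_similarity,
    epitope_groups,
    estimate_epitopes,
    normalized_levenshtein,
    paratope_distance,
    paratype_identity,
    predict_common_epitope,
)
from gcrepertoire.simulate import LymphNodeConfig, generate_lymph_node, generate_paratopes


def brute_force_levenshtein(a: str, b: str) -> int:
    """Full-matrix DP oracle."""
    m, n = len(a), len(b)
    d = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        d[i][0] = i
    for j in range(n + 1):
        d[0][j] = j
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            d[i][j] = min(d[i - 1][j] + 1, d[i][j - 1] + 1,
                          d[i - 1][j - 1] + (a[i - 1] != b[j - 1]))
    return d[m][n]


class TestNormalizedLevenshtein:
    @pytest.mark.parametrize("a, b, expected", [
        ("ACGT", "ACGT", 0.0),
        ("ACGT", "ACGA", 2 / 9),
        ("A", "", 1.0),
        ("", "", 0.0),
    ])
    def test_values(self, a, b, expected):
        assert normalized_levenshtein(a, b) == pytest.approx(expected)

    @given(st.text(alphabet="ACGT", max_size=12),
           st.text(alphabet="ACGT", max_size=12),
           st.text(alphabet="ACGT", max_size=12))
    @settings(max_examples=200, derandomize=True)
    def test_metric_properties_and_oracle(self, a, b, c):
        dab = normalized_levenshtein(a, b)
        assert dab == pytest.approx(normalized_levenshtein(b, a))
        assert 0.0 <= dab <= 1.0
        assert (dab == 0.0) == (a == b)
        lev = brute_force_levenshtein(a, b)
        if a or b:
            assert dab == pytest.approx(2 * lev / (len(a) + len(b) + lev))
        # triangle inequality
        dac = normalized_levenshtein(a, c)
        dcb = normalized_levenshtein(c, b)
        assert dab <= dac + dcb + 1e-12


def profile(cid, cdrs, paratope_positions=None, aa=None, coords=None,
            numbering=None):
    """A hand-built paratope profile; residues are the concatenated CDRs
    unless a full sequence is given."""
    aa = aa if aa is not None else "".join(cdrs)
    n = len(aa)
    probs = np.full(n, 0.1)
    mask = np.zeros(n, dtype=bool)
    if paratope_positions is not None:
        mask[list(paratope_positions)] = True
        probs[list(paratope_positions)] = 0.9
    return ParatopeProfile(
        clone_id=cid, aa_sequence=aa, cdr_seqs=tuple(cdrs),
        residue_probs=probs, paratope_mask=mask,
        coords=np.asarray(coords, dtype=float) if coords is not None else None,
        numbering=list(numbering) if numbering is not None
        else list(range(n)))


class TestCDRSimilarity:
    def test_identical(self):
        p = profile("a", ("GYTFTGYY", "INPNSGGT", "ARDTTGYWG"))
        assert cdr_similarity(p, p) == pytest.approx(1.0)

    def test_h3_distance_only(self):
        # H3 pair at normalized distance exactly 0.3 (lengths 9+8, Lev 3)
        h3a, h3b = "ARDTTGYWG", "ARDAAGYW"
        assert brute_force_levenshtein(h3a, h3b) == 3
        assert normalized_levenshtein(h3a, h3b) == pytest.approx(0.3)
        a = profile("a", ("GYTFTGYY", "INPNSGGT", h3a))
        b = profile("b", ("GYTFTGYY", "INPNSGGT", h3b))
        assert cdr_similarity(a, b) == pytest.approx(0.9)

    def test_fully_different_cdrs_hit_the_metric_floor(self):
        # equal-length strings cap the normalized distance at 2/3, so the
        # similarity floor for non-degenerate CDR triples is 1/3
        a = profile("a", ("AAAA", "CCCC", "DDDD"))
        b = profile("b", ("GGGG", "HHHH", "KKKK"))
        assert cdr_similarity(a, b) == pytest.approx(1 / 3)

    def test_missing_cdr_rejected(self):
        a = profile("a", ("AAAA", "", "DDDD"))
        b = profile("b", ("AAAA", "CCCC", "DDDD"))
        with pytest.raises(ValueError):
            cdr_similarity(a, b)


class TestParatypeIdentity:
    def test_identical(self):
        p = profile("a", ("GYTF", "INPN", "ARDT"), paratope_positions=range(6))
        assert paratype_identity(p, p) == pytest.approx(1.0)

    def test_smaller_paratope_denominator(self):
        # a: 4 paratope residues, b: 6; 3 identical -> 3/4 = 0.75
        aa = "GYTFINPNARDT"
        a = profile("a", ("GYTF", "INPN", "ARDT"),
                    paratope_positions=[0, 1, 2, 3], aa=aa)
        b = profile("b", ("GYTFINPNARDT"[:4], aa[4:8], aa[8:]),
                    paratope_positions=[0, 1, 2, 5, 6, 7],
                    aa="GYTAINPNARDT")  # position 3 differs
        assert paratype_identity(a, b) == pytest.approx(0.75)

    def test_disjoint_positions(self):
        aa = "GYTFINPN"
        a = profile("a", (aa[:4], aa[4:], "AAAA"), paratope_positions=[0, 1],
                    aa=aa)
        b = profile("b", (aa[:4], aa[4:], "AAAA"), paratope_positions=[6, 7],
                    aa=aa)
        assert paratype_identity(a, b) == pytest.approx(0.0)

    def test_empty_paratope_excluded_with_warning(self):
        aa = "GYTF"
        a = profile("a", (aa, aa, aa), paratope_positions=[], aa=aa)
        b = profile("b", (aa, aa, aa), paratope_positions=[0], aa=aa)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            assert paratype_identity(a, b) is None
        assert any("paratope" in str(w.message) for w in caught)


class TestAbligity:
    def square(self, cid, aa, side=3.0):
        # four paratope residues on a square: C(4,3) = 4 triangle tokens
        coords = [(0, 0, 0), (side, 0, 0), (side, side, 0), (0, side, 0)]
        return profile(cid, (aa[:2], aa[2:3], aa[3:]),
                       paratope_positions=range(4), aa=aa, coords=coords)

    def test_identical_structures(self):
        p = self.square("a", "STKD")
        assert abligity_score(p, p) == pytest.approx(1.0)

    def test_disjoint_chemical_classes(self):
        a = self.square("a", "DDDD")  # all acidic
        b = self.square("b", "KKKK")  # all basic
        assert abligity_score(a, b) == pytest.approx(0.0)

    def test_single_moved_residue_hand_count(self):
        """Moving one residue far away breaks the 3 triples that contain
        it: intersection 1, union 4 + 4 - 1 = 7."""
        a = self.square("a", "STKD", side=3.0)
        b = profile("b", ("ST", "K", "D"), paratope_positions=range(4),
                    aa="STKD",
                    coords=[(0, 0, 0), (3, 0, 0), (3, 3, 0), (0, 9, 0)])
        assert abligity_score(a, b) == pytest.approx(1 / 7)

    def test_two_shared_tokens_hand_count(self):
        """Two 4-residue paratopes sharing exactly 2 of their triple
        tokens score 2 / 6 by Tanimoto.

        Hand enumeration for a (S T K S at the coordinates below, 1 A
        bins): d01=4, d02=d03=d12=d13=3.6, d23=6, so the token multiset is
        {(KSS-like, 3,3,4): 1, (SSS, 3,3,4): 1, (KSS-like, 3,3,6): 2}.
        b moves residue 3 so that d03 stays in bin 3 and d23 in bin 6 but
        d13 shifts to bin 5: triples 012 and 023 keep their tokens
        (intersection 2), union is 6."""
        a = profile("a", ("ST", "K", "S"), paratope_positions=range(4),
                    aa="STKS",
                    coords=[(0, 0, 0), (4, 0, 0), (2, 3, 0), (2, -3, 0)])
        b = profile("b", ("ST", "K", "S"), paratope_positions=range(4),
                    aa="STKS",
                    coords=[(0, 0, 0), (4, 0, 0), (2, 3, 0), (-1.1, -2.9, 0)])
        assert abligity_score(a, b) == pytest.approx(2 / 6)
        assert abligity_score(a, b) == pytest.approx(self._tanimoto_oracle(a, b))

    @staticmethod
    def _tanimoto_oracle(a, b, bin_width=1.0):
        from collections import Counter

        def toks(p):
            idx = np.flatnonzero(p.paratope_mask)
            out = Counter()
            from gcrepertoire.convergence import CHEMICAL_CLASS
            for i, j, k in itertools.combinations(idx.tolist(), 3):
                cls = tuple(sorted(CHEMICAL_CLASS[p.aa_sequence[q]]
                                   for q in (i, j, k)))
                d = tuple(sorted(
                    int(np.linalg.norm(np.asarray(p.coords[x]) -
                                       np.asarray(p.coords[y])) // bin_width)
                    for x, y in ((i, j), (i, k), (j, k))))
                out[(cls, d)] += 1
            return out

        ta, tb = toks(a), toks(b)
        return sum((ta & tb).values()) / sum((ta | tb).values())

    def test_abstains_without_coords_or_small_paratope(self):
        a = self.square("a", "STKD")
        no_coords = profile("b", ("ST", "K", "D"),
                            paratope_positions=range(4), aa="STKD")
        assert abligity_score(a, no_coords) is None
        tiny = profile("c", ("ST", "K", "D"), paratope_positions=[0, 1],
                       aa="STKD", coords=[(0, 0, 0)] * 4)
        assert abligity_score(a, tiny) is None


class TestPredictCommonEpitope:
    def _pair(self, h3_a="ARDTTGYWG", h3_b="ARDTTGYWG", positions=range(6),
              coords_b=None):
        coords = [(1.5 * i, 0, 0) for i in range(40)]
        a = profile("a", ("GYTFTGYY", "INPNSGGT", h3_a),
                    paratope_positions=positions, coords=coords[:16 + len(h3_a)])
        b = profile("b", ("GYTFTGYY", "INPNSGGT", h3_b),
                    paratope_positions=positions,
                    coords=(coords_b or coords)[:16 + len(h3_b)])
        return a, b

    def test_identical_profiles_three_votes(self):
        a, b = self._pair()
        pair = predict_common_epitope(a, b)
        assert pair.votes == 3 and pair.predicted

    def test_two_votes_suffice(self):
        # degrade the structural metric only: far-apart coordinates
        far = [(100 * i, 50 * i, 0) for i in range(40)]
        a, b = self._pair(coords_b=far)
        pair = predict_common_epitope(a, b)
        assert pair.abligity_score is not None
        assert pair.abligity_score <= 0.26
        assert pair.votes == 2 and pair.predicted

    def test_cdr3_length_gate(self):
        a, b = self._pair(h3_b="ARDTTGYW")  # one residue shorter
        pair = predict_common_epitope(a, b)
        assert not pair.same_cdr3_length
        assert not pair.predicted

    def test_abstention_cannot_be_compensated(self):
        # no coordinates and an empty-paratope partner: only the CDR
        # metric can vote -> one vote -> not predicted
        aa = "GYTFTGYYINPNSGGTARDTTGYWG"
        a = profile("a", ("GYTFTGYY", "INPNSGGT", "ARDTTGYWG"),
                    paratope_positions=[], aa=aa)
        b = profile("b", ("GYTFTGYY", "INPNSGGT", "ARDTTGYWG"),
                    paratope_positions=[0, 1, 2], aa=aa)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pair = predict_common_epitope(a, b)
        assert pair.votes == 1 and not pair.predicted

    def test_symmetric(self):
        a, b = self._pair(h3_b="ARDAAGYWG")
        pab = predict_common_epitope(a, b)
        pba = predict_common_epitope(b, a)
        assert pab.cdr_similarity == pytest.approx(pba.cdr_similarity)
        assert pab.votes == pba.votes and pab.predicted == pba.predicted


class TestCategorizeAndDistance:
    def _clone(self, cid, v, j, junction):
        return Clone(cid, v.split("-")[0], v, j, len(junction), [cid], 1, 0.1,
                     junction, cid)

    def test_same_clone_multi_gc(self):
        clones = {
            "a": self._clone("a", "IGHV1-2", "IGHJ4", "TGTGCTAAATGG"),
            "b": self._clone("b", "IGHV1-2", "IGHJ4", "TGTGCTAAATGG"),
        }
        pair = ConvergencePair("a", "b", 1.0, 1.0, 1.0, True, 3, True)
        assert categorize_pair(pair, clones) == "same_clone_multi_gc"

    def test_same_vj_divergent_cdr3(self):
        clones = {
            "a": self._clone("a", "IGHV1-2", "IGHJ4", "TGTGCTAAATGG"),
            "b": self._clone("b", "IGHV1-2", "IGHJ4", "TGTTTTCCCTGG"),
        }
        pair = ConvergencePair("a", "b", 0.9, 0.8, 0.3, True, 3, True)
        assert categorize_pair(pair, clones) == "same_vj_divergent_cdr3"

    def test_different_v_or_j(self):
        clones = {
            "a": self._clone("a", "IGHV1-2", "IGHJ4", "TGTGCTAAATGG"),
            "b": self._clone("b", "IGHV1-2", "IGHJ6", "TGTGCTAAATGG"),
        }
        pair = ConvergencePair("a", "b", 1.0, 1.0, 1.0, True, 3, True)
        assert categorize_pair(pair, clones) == "different_v_or_j"

    def test_paratope_distance(self):
        pair = ConvergencePair("a", "b", 0.9, 0.8, None, True, 2, True)
        assert paratope_distance(pair) == pytest.approx(0.15)
        identical = ConvergencePair("a", "b", 1.0, 1.0, 1.0, True, 3, True)
        assert paratope_distance(identical) == pytest.approx(0.0)
        worst = ConvergencePair("a", "b", 0.0, 0.0, 0.0, True, 0, False)
        assert paratope_distance(worst) == pytest.approx(1.0)
        undefined = ConvergencePair("a", "b", 0.9, None, None, True, 1, False)
        with pytest.raises(ValueError):
            paratope_distance(undefined)


class TestEstimateEpitopes:
    def test_scalings(self):
        groups = [set([str(i)]) for i in range(5000)]
        raw, corrected = estimate_epitopes(groups, pair_recall=0.1)
        assert raw == 5000 and corrected == pytest.approx(500)
        raw, corrected = estimate_epitopes(groups, pair_recall=1.0)
        assert corrected == raw
        assert estimate_epitopes([], 0.1) == (0, 0.0)
        with pytest.raises(ValueError):
            estimate_epitopes(groups, pair_recall=0.0)


class TestPlantedRecovery:
    def test_planted_groups_recovered_at_low_noise(self):
        """Fifty clones planted in five epitope groups, low paratope
        noise: at least 90% of within-group pairs are predicted and at
        least 4 of the 5 groups come back as connected components."""
        cfg = LymphNodeConfig(seqs_per_sample=500, n_clones_per_gc=80,
                              n_epitopes=5, epitope_group_size=10,
                              paratope_noise=0.02, seed=5)
        records, truth = generate_lymph_node(cfg)
        clones = group_clones(records)
        profiles = generate_paratopes(clones, truth, cfg)
        assign = truth.clone_assignments
        group_of = dict(zip(truth.clones["clone"],
                            truth.clones["epitope_group"]))
        by_id = {c.clone_id: c for c in clones}
        label = {c.clone_id: group_of.get(assign[c.representative_id], -1)
                 for c in clones}
        groups, pairs, _ = epitope_groups(profiles, by_id,
                                          rank_threshold=10_000)
        byg = {}
        for cid, g in label.items():
            if g >= 0:
                byg.setdefault(g, []).append(cid)
        predicted = {frozenset((p.clone_a, p.clone_b)) for p in pairs}
        tp = fn = 0
        for members in byg.values():
            for a, b in itertools.combinations(members, 2):
                hit = frozenset((a, b)) in predicted
                tp += hit
                fn += not hit
        assert tp / (tp + fn) >= 0.9
        recovered = sum(
            1 for members in byg.values()
            if any(set(members) <= comp for comp in groups))
        assert recovered >= 4
        # no spurious merging of unrelated clones into planted groups
        for p in pairs:
            assert label[p.clone_a] == label[p.clone_b]

    def test_no_predicted_pairs_means_singletons(self, small_clones):
        groups, pairs, _ = epitope_groups([], {c.clone_id: c
                                               for c in small_clones})
        assert not pairs and not groups
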