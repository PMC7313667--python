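"""NG86 dS, codon alignment, dS trees, calibration dating, bootstrap."""

from __future__ import annotations

import itertools
import math
import random

import dendropy
import numpy as np
import pytest

from msy.clock import (
    AgeEstimate,
    SaturationError,
    align_codons,
    bootstrap_age,
    calibrate_and_date,
    codon_pair_score,
    concatenate_and_tree,
    ng86_ds,
    ng86_site_counts,
    pairwise_ds_matrix,
)

# ---------------------------------------------------------------------------
# independent brute-force NG86 oracle (no shared code with msy.clock)
# ---------------------------------------------------------------------------

_ORACLE_BASES = "TCAG"
_ORACLE_CODE = {}
_aas = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, (_a, _b, _c) in enumerate(itertools.product(_ORACLE_BASES, repeat=3)):
    _ORACLE_CODE[_a + _b + _c] = _aas[_i]


def oracle_sites(codon):
    syn = 0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            nb = codon[:pos] + b + codon[pos + 1 :]
            if _ORACLE_CODE[nb] == _ORACLE_CODE[codon] and _ORACLE_CODE[nb] != "*":
                syn += 1
    return syn / 3.0


def oracle_pair(a, b):
    """Average Sd/Nd over all substitution orderings, skipping stop paths."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff):
        cur, sd, nd, blocked = a, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if _ORACLE_CODE[nxt] == "*" and nxt != b:
                blocked = True
            if _ORACLE_CODE[cur] == _ORACLE_CODE[nxt] and _ORACLE_CODE[nxt] != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((blocked, sd, nd))
    ok = [(s, n) for bl, s, n in results if not bl] or [(s, n) for _, s, n in results]
    return sum(r[0] for r in ok) / len(ok), sum(r[1] for r in ok) / len(ok)


def oracle_counts(seq_a, seq_b):
    S = N = Sd = 0.0
    for i in range(0, len(seq_a), 3):
        a, b = seq_a[i : i + 3], seq_b[i : i + 3]
        if "-" in a or "-" in b or _ORACLE_CODE[a] == "*" or _ORACLE_CODE[b] == "*":
            continue
        S += (oracle_sites(a) + oracle_sites(b)) / 2
        N += 3 - (oracle_sites(a) + oracle_sites(b)) / 2
        sd, _nd = oracle_pair(a, b)
        Sd += sd
    return S, N, Sd


def _random_codon_seq(rng, n_codons):
    codons = [c for c in _ORACLE_CODE if _ORACLE_CODE[c] != "*"]
    return "".join(rng.choice(codons) for _ in range(n_codons))


def _mutated(rng, seq, n_changes):
    s = list(seq)
    for _ in range(n_changes):
        i = rng.randrange(len(s))
        s[i] = rng.choice([b for b in "ACGT" if b != s[i]])
        if _ORACLE_CODE["".join(s[3 * (i // 3) : 3 * (i // 3) + 3])] == "*":
            s[i] = seq[i]  # keep stop-free
    return "".join(s)


class TestNg86:
    def test_site_count_examples(self):
        # TTT (Phe): only TTT->TTC of nine neighbors is synonymous
        assert ng86_site_counts("TTT")[0] == pytest.approx(1 / 3)
        # GGG (Gly): third position fourfold degenerate
        assert ng86_site_counts("GGG")[0] == pytest.approx(1.0)

    def test_worked_example(self):
        est = ng86_ds("GGGGGGGGGTTT", "GGAGGGGGGTTT")
        assert est.Sd == pytest.approx(1.0)
        assert est.S == pytest.approx(10 / 3)
        assert est.ps == pytest.approx(0.3)
        assert est.ds == pytest.approx(-0.75 * math.log(0.6), abs=1e-12)

    def test_identical_sequences_zero(self):
        assert ng86_ds("ATGGCT", "ATGGCT").ds == 0.0

    def test_site_conservation_and_symmetry(self):
        rng = random.Random(3)
        for _ in range(20):
            a = _random_codon_seq(rng, 12)
            b = _mutated(rng, a, 6)
            ab, ba = ng86_ds(a, b), ng86_ds(b, a)
            assert ab.S + ab.N == pytest.approx(3 * ab.n_codons, abs=1e-9)
            assert ab.ds == pytest.approx(ba.ds, abs=1e-12)
            assert ab.ds >= 0

    def test_matches_brute_force_oracle(self):
        rng = random.Random(4)
        checked = 0
        while checked < 40:
            n = rng.randrange(8, 24)
            a = _random_codon_seq(rng, n)
            b = _mutated(rng, a, rng.randrange(0, n // 2))
            S, N, Sd = oracle_counts(a, b)
            if Sd / S >= 0.7:  # keep clear of the Jukes-Cantor ceiling
                continue
            est = ng86_ds(a, b)
            assert est.S == pytest.approx(S, abs=1e-10)
            assert est.N == pytest.approx(N, abs=1e-10)
            assert est.Sd == pytest.approx(Sd, abs=1e-10)
            ds = -0.75 * math.log(1 - 4 * (Sd / S) / 3)
            assert est.ds == pytest.approx(ds, abs=1e-10)
            checked += 1

    def test_gap_and_stop_columns_excluded(self):
        est = ng86_ds("ATG---GGG", "ATGGCTGGG")
        assert est.n_codons == 2 and est.n_excluded == 1
        assert est.ds == 0.0

    def test_saturation_error(self):
        # all fourfold third positions differing: ps close to 1
        a = "GGT" * 30
        b = "GGA" * 30
        with pytest.raises(SaturationError):
            ng86_ds(a, b)


# ---------------------------------------------------------------------------
# codon alignment
# ---------------------------------------------------------------------------


def _oracle_best_score(a, b, gap=-4):
    """Exhaustive recursion over all codon alignments of tiny inputs."""

    def rec(i, j):
        if i == len(a) and j == len(b):
            return 0
        best = -(10**9)
        if i < len(a) and j < len(b):
            best = max(best, codon_pair_score(a[i], b[j]) + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, gap + rec(i, j + 1))
        return best

    return rec(0, 0)


class TestAlignCodons:
    def test_identical_inputs_unchanged(self):
        aln = align_codons({"a": "ATGGCT", "b": "ATGGCT"})
        assert aln.seqs == {"a": "ATGGCT", "b": "ATGGCT"}

    def test_single_codon_insertion_single_triplet_gap(self):
        aln = align_codons({"a": "ATGAAAGCT", "b": "ATGGCT"})
        assert aln.seqs["a"] == "ATGAAAGCT"
        assert aln.seqs["b"].count("-") == 3
        assert "---" in aln.seqs["b"]

    def test_alignment_length_multiple_of_three(self):
        aln = align_codons({"a": "ATGGCTAAA", "b": "ATGAAA", "c": "ATGGCTAAAGGG"})
        lengths = {len(s) for s in aln.seqs.values()}
        assert len(lengths) == 1 and lengths.pop() % 3 == 0

    def test_score_matches_exhaustive_oracle(self):
        rng = random.Random(6)
        from msy.clock import _pairwise_codon_align

        for _ in range(15):
            a = [_random_codon_seq(rng, 1) for _ in range(rng.randrange(1, 6))]
            b = [_random_codon_seq(rng, 1) for _ in range(rng.randrange(1, 6))]
            cols = _pairwise_codon_align(a, b)
            score = sum(
                codon_pair_score(x, y) if x and y else -4 for x, y in cols
            )
            assert score == _oracle_best_score(a, b)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError):
            align_codons({"a": "ATGTAAGCT", "b": "ATGGCTGCT"})


# ---------------------------------------------------------------------------
# trees and dating
# ---------------------------------------------------------------------------


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


class TestDsTree:
    def test_two_taxa_lengths_sum_to_pairwise_ds(self):
        tree = _tree("(X,Y);")
        fitted = concatenate_and_tree({frozenset(("X", "Y")): 0.4}, tree)
        total = sum(e.length for e in fitted.preorder_edge_iter() if e.length)
        assert total == pytest.approx(0.4, abs=1e-9)

    def test_additive_matrix_recovered_exactly(self):
        # known branch lengths on ((X,Y),OutA,OutB) unrooted
        bx, by, ba, bb, bi = 0.1, 0.12, 0.3, 0.5, 0.05
        d = {
            frozenset(("X", "Y")): bx + by,
            frozenset(("X", "OutA")): bx + bi + ba,
            frozenset(("Y", "OutA")): by + bi + ba,
            frozenset(("X", "OutB")): bx + bi + bb,
            frozenset(("Y", "OutB")): by + bi + bb,
            frozenset(("OutA", "OutB")): ba + bb,
        }
        tree = _tree("(((X,Y),OutA),OutB);")
        fitted = concatenate_and_tree(d, tree)
        # all leaf-pair path sums must reproduce the generating matrix
        pdm = fitted.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in fitted.taxon_namespace}
        for pair, expected in d.items():
            a, b = tuple(pair)
            assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(expected, abs=1e-9)

    def test_negative_branch_clamped_to_zero(self):
        # distances violating the triangle structure force a zero branch
        d = {
            frozenset(("X", "Y")): 0.0,
            frozenset(("X", "OutA")): 0.4,
            frozenset(("Y", "OutA")): 0.4,
        }
        tree = _tree("((X,Y),OutA);")
        fitted = concatenate_and_tree(d, tree)
        lengths = [e.length for e in fitted.preorder_edge_iter() if e.length is not None]
        assert all(l >= 0 for l in lengths)


class TestCalibrateAndDate:
    def _fitted(self, d):
        return concatenate_and_tree(d, _tree("((X,Y),OutA);"))

    def test_arithmetic_example(self):
        # per-lineage calibration path dS 0.4 (pairwise 0.8) over 200 Myr
        # and dS(X,Y)=0.4 => rate 0.002/lineage, age (0.4/2)/0.002 = 100
        d = {
            frozenset(("X", "Y")): 0.4,
            frozenset(("X", "OutA")): 0.8,
            frozenset(("Y", "OutA")): 0.8,
        }
        est = calibrate_and_date(self._fitted(d), [("X", "OutA", 200.0)])
        assert est.age == pytest.approx(100.0, abs=1e-6)
        assert est.rate == pytest.approx(0.002, abs=1e-9)

    def test_zero_divergence_zero_age(self):
        d = {
            frozenset(("X", "Y")): 0.0,
            frozenset(("X", "OutA")): 0.3,
            frozenset(("Y", "OutA")): 0.3,
        }
        est = calibrate_and_date(self._fitted(d), [("X", "OutA", 150.0)])
        assert est.age == 0.0

    def test_rescaling_ds_leaves_age_unchanged(self):
        base = {
            frozenset(("X", "Y")): 0.2,
            frozenset(("X", "OutA")): 0.5,
            frozenset(("Y", "OutA")): 0.5,
        }
        est1 = calibrate_and_date(self._fitted(base), [("X", "OutA", 100.0)])
        scaled = {k: 3.0 * v for k, v in base.items()}
        est2 = calibrate_and_date(self._fitted(scaled), [("X", "OutA", 100.0)])
        assert est1.age == pytest.approx(est2.age, rel=1e-9)

    def test_age_clamped_to_calibration(self):
        d = {
            frozenset(("X", "Y")): 2.0,
            frozenset(("X", "OutA")): 0.2,
            frozenset(("Y", "OutA")): 0.2,
        }
        est = calibrate_and_date(self._fitted(d), [("X", "OutA", 100.0)])
        assert est.age == 100.0


class TestBootstrap:
    def test_identical_sequences_degenerate_ci(self):
        seqs = {"X": "ATGGCT" * 20, "Y": "ATGGCT" * 20, "OutA": "ATGGCT" * 20}
        est = bootstrap_age(
            seqs, _tree("((X,Y),OutA);"), [("X", "OutA", 100.0)], n_bootstrap=25, seed=0
        )
        assert est.age == 0.0
        assert est.ci_low == 0.0 and est.ci_high == 0.0

    def test_ci_width_shrinks_with_length(self):
        from msy.clock import codon_string
        from msy.simulate import ClockSimSpec, dated_topology, simulate_gametolog_pair

        spec = ClockSimSpec(true_age=100.0, seed=2)
        widths = []
        for n_codons in (100, 1000):
            rng = np.random.default_rng(12)
            seqs = {
                t: codon_string(arr)
                for t, arr in simulate_gametolog_pair(spec, n_codons, rng).items()
            }
            est = bootstrap_age(
                seqs, dated_topology(spec), spec.calibrations(), n_bootstrap=60, seed=3
            )
            widths.append(est.ci_high - est.ci_low)
        assert widths[1] < widths[0]

    def test_too_short_concatenation_rejected(self):
        seqs = {"X": "ATG" * 10, "Y": "ATG" * 10, "OutA": "ATG" * 10}
        with pytest.raises(ValueError):
            bootstrap_age(seqs, _tree("((X,Y),OutA);"), [("X", "OutA", 1.0)], seed=0)


class TestAgeEstimateInvariants:
    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            AgeEstimate(age=-1.0)


def test_pairwise_ds_matrix_keys():
    base = "GGTGCTACTCCTGTTGCA" * 2
    seqs = {"X": base, "Y": base[:-1] + "T", "Z": "GGA" + base[3:]}
    d = pairwise_ds_matrix(seqs)
    assert set(d) == {
        frozenset(("X", "Y")),
        frozenset(("X", "Z")),
        frozenset(("Y", "Z")),
    }
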