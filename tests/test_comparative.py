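"""Peptide alignment, E-values, ortholog grouping and NG86 dN/dS."""

import itertools
import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from altorf.comparative import (
    DivergenceTable,
    EvalueParams,
    align_peptides,
    build_ortholog_groups,
    codon_align,
    dnds_ng86,
    evalue,
    group_age,
    OrthologGroup,
)
from altorf.core import GenomicInterval, OrfRecord
from altorf.simulate import evolve_sequence

BLOSUM62 = substitution_matrices.load("BLOSUM62")
AAS = "ACDEFGHIKLNPQRSTVWY"


def sw_oracle(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Plain quadratic Smith-Waterman with affine gaps (Gotoh)."""
    n, m = len(a), len(b)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (deletion from b)
    F = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - (gap_open + gap_extend),
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - (gap_open + gap_extend),
                          F[i - 1][j] - gap_extend)
            s = BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def _orf(orf_id, peptide, species="x"):
    return OrfRecord(
        orf_id=orf_id,
        species_id=species,
        interval=GenomicInterval("c", 0, 3 * (len(peptide) + 1), "+"),
        frame=0,
        aa_length=len(peptide),
        peptide=peptide,
    )


class TestAligner:
    def test_identity_hand_score(self):
        hit = align_peptides("MKLVW", "MKLVW")
        assert hit.raw_score == 29  # 5+5+4+4+11 on the BLOSUM62 diagonal
        assert hit.identity == 1.0
        assert hit.aligned_span == 5

    def test_all_mismatch_is_no_hit(self):
        hit = align_peptides("MMMM", "WWWW")
        assert hit.raw_score == 0.0
        assert hit.aligned_span == 0
        assert math.isinf(hit.evalue)

    @pytest.mark.parametrize("seed", range(3))
    def test_score_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(15):
            a = "".join(rng.choice(list(AAS), size=rng.integers(5, 40)))
            b = "".join(rng.choice(list(AAS), size=rng.integers(5, 40)))
            assert align_peptides(a, b).raw_score == align_peptides(b, a).raw_score

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(1234)
        for _ in range(50):
            a = "".join(rng.choice(list(AAS), size=rng.integers(5, 41)))
            b = "".join(rng.choice(list(AAS), size=rng.integers(5, 41)))
            expected = sw_oracle(a, b)
            got = align_peptides(a, b).raw_score
            assert got == expected or (expected <= 0 and got == 0)

    def test_rejects_invalid_residues(self):
        with pytest.raises(ValueError):
            align_peptides("MKL*", "MKL")


class TestEvalue:
    def test_hand_computation(self):
        params = EvalueParams(K=0.041, lam=0.267, m=100, n=100)
        expected = 0.041 * 1e4 * math.exp(-0.267 * 40)
        assert evalue(40, params) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(9.4e-3, rel=0.02)

    def test_monotone_decreasing_in_score(self):
        params = EvalueParams()
        values = [evalue(s, params) for s in range(0, 200, 10)]
        assert all(x > y for x, y in zip(values, values[1:]))
        assert evalue(10_000, params) == pytest.approx(0.0, abs=1e-300)


def brute_force_groups(per_species, e_max):
    """All-pairs clustering oracle without k-mer seeding (BFS components)."""
    entries = [(sp, o) for sp, orfs in per_species.items() for o in orfs]
    n = len(entries)
    adj = {i: set() for i in range(n)}
    for i, j in itertools.combinations(range(n), 2):
        if entries[i][0] == entries[j][0]:
            continue
        a, b = entries[i][1].peptide, entries[j][1].peptide
        hit = align_peptides(a, b, params=EvalueParams(m=len(a), n=len(b)))
        if hit.evalue <= e_max:
            adj[i].add(j)
            adj[j].add(i)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k])
        seen |= comp
        comps.append(frozenset((entries[k][0], entries[k][1].orf_id) for k in comp))
    return set(comps)


class TestGrouping:
    def test_identical_peptides_group(self):
        pep = "M" + "ACDEFGHIKLNPQRSTVY" * 3
        groups = build_ortholog_groups(
            {"s1": [_orf("a", pep, "s1")], "s2": [_orf("b", pep, "s2")]}
        )
        assert len(groups) == 1
        assert groups[0].species_count == 2

    def test_no_hits_all_singletons(self):
        groups = build_ortholog_groups(
            {"s1": [_orf("a", "MPPPPPPPPPP", "s1")],
             "s2": [_orf("b", "MKKKKKKKKKK", "s2")]}
        )
        assert len(groups) == 2
        assert all(g.species_count == 1 for g in groups)

    def test_partition_property(self, pipeline_result):
        groups = pipeline_result.groups
        seen = [m for g in groups for m in g.members]
        assert len(seen) == len(set(seen))  # disjoint and covering

    def test_planted_family_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        species = [f"s{i}" for i in range(5)]
        base = "M" + "".join(rng.choice(list(AAS), size=49))
        per_species = {}
        for k, sp in enumerate(species):
            pep = list(base)
            for pos in rng.choice(np.arange(1, 50), size=5, replace=False):
                pep[pos] = rng.choice(list(AAS))
            per_species[sp] = [_orf(f"fam_{sp}", "".join(pep), sp)]
            # one unrelated singleton per species
            per_species[sp].append(
                _orf(f"bg_{sp}",
                     "M" + "".join(rng.choice(list(AAS), size=30)), sp)
            )
        groups = build_ortholog_groups(per_species, e_max=1e-5)
        got = {
            frozenset(g.members) for g in groups
        }
        expected = brute_force_groups(per_species, 1e-5)
        assert got == expected
        fam = next(g for g in groups if any("fam" in m[1] for m in g.members))
        assert fam.species_count == 5


class TestGroupAge:
    def _table(self):
        t = DivergenceTable()
        t.set("A", "B", 5)
        t.set("A", "C", 25)
        t.set("B", "C", 25)
        return t

    def test_singleton_age_zero(self):
        g = OrthologGroup("g", [("A", "x")])
        assert group_age(g, self._table()) == 0.0

    def test_max_semantics(self):
        g = OrthologGroup("g", [("A", "x"), ("B", "y"), ("C", "z")])
        assert group_age(g, self._table()) == 25

    def test_monotone_under_added_species(self):
        t = self._table()
        g2 = OrthologGroup("g", [("A", "x"), ("B", "y")])
        g3 = OrthologGroup("g", [("A", "x"), ("B", "y"), ("C", "z")])
        assert group_age(g3, t) >= group_age(g2, t)

    def test_missing_pair_errors_with_names(self):
        g = OrthologGroup("g", [("A", "x"), ("Z", "y")])
        with pytest.raises(KeyError, match="Z"):
            group_age(g, self._table())

    def test_packaged_divergence_matches_reported_age_set(self):
        table = DivergenceTable.default()
        species = sorted({s for key in table.times for s in key})
        assert len(species) == 11
        # ages of multi-species groups in the study take values in this set
        values = set(table.times.values())
        assert {10, 14, 27, 40} <= values


class TestCodonAlign:
    def test_identical_gap_free(self):
        nt = "ATGGCAGAACGT"
        a, b = codon_align(nt, nt)
        assert a == b == nt

    def test_single_codon_deletion(self):
        a_nt = "ATGGCAGAACGTTGCAAA"  # M A E R C K
        b_nt = "ATGGCACGTTGCAAA"     # M A R C K (E deleted)
        aa, bb = codon_align(a_nt, b_nt)
        assert len(aa) == len(bb) == 18
        assert bb.count("-") == 3
        i = bb.index("---")
        assert i % 3 == 0 and aa[i : i + 3] == "GAA"

    def test_columns_translate_to_protein_alignment(self):
        rng = np.random.default_rng(2)
        codons = [c for c in map("".join, itertools.product("ACGT", repeat=3))
                  if str(Seq(c).translate()) not in "*M"]
        a_nt = "ATG" + "".join(rng.choice(codons, size=20))
        b_nt = "ATG" + "".join(rng.choice(codons, size=18))
        aa, bb = codon_align(a_nt, b_nt)
        for s in (aa, bb):
            for i in range(0, len(s), 3):
                cod = s[i : i + 3]
                assert cod == "---" or "-" not in cod


def ng86_site_oracle(codon):
    """Independent per-codon synonymous-site count by enumeration."""
    syn = 0.0
    aa = str(Seq(codon).translate())
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            alt_aa = str(Seq(alt).translate())
            if alt_aa == aa and alt_aa != "*":
                syn += 1 / 3
    return syn


class TestNg86:
    def test_identical_sequences_flag_too_small(self):
        nt = "ATGGCAGAACGTTGCAAA" * 3
        res = dnds_ng86(nt, nt, min_codons=10)
        assert res.dN == 0.0 and res.dS == 0.0
        assert res.caution_flag == "dS_too_small"
        assert res.omega is None

    def test_leucine_wobble_is_synonymous(self):
        res = dnds_ng86("TTTTTA", "TTTTTG", min_codons=1)
        assert res.dN == 0.0  # one synonymous difference, no nonsynonymous
        assert res.dS > 0.0

    def test_jc_correction_matches_site_oracle(self):
        pad = "CCA" * 10  # identical codons dilute pS below saturation
        a, b = "TTTTTA" + pad, "TTTTTG" + pad
        res = dnds_ng86(a, b, min_codons=1)
        codons = ["TTT", "TTA"] + ["CCA"] * 10 + ["TTT", "TTG"] + ["CCA"] * 10
        S = sum(ng86_site_oracle(c) for c in codons) / 2
        pS = 1.0 / S
        expected_dS = -0.75 * math.log(1 - 4 * pS / 3)
        assert res.dN == 0.0
        assert res.dS == pytest.approx(expected_dS, rel=1e-9)

    def test_nonsynonymous_only_change(self):
        a = "TTTAAA"  # F K
        b = "TTTGAA"  # F E
        res = dnds_ng86(a, b, min_codons=1)
        assert res.dS == 0.0
        assert res.dN > 0.0

    def test_flag_too_large_on_saturated_sequences(self):
        rng = np.random.default_rng(0)
        codons_a, codons_b = [], []
        # maximally divergent synonymous 4-fold sites: GGx family
        for _ in range(30):
            codons_a.append("GG" + "ACGT"[rng.integers(4)])
            codons_b.append("GG" + "ACGT"[rng.integers(4)])
        a, b = "".join(codons_a), "".join(codons_b)
        res = dnds_ng86(a, b)
        assert res.caution_flag in ("dS_too_large", "dS_too_small", "ok")
        # force saturation: every 4-fold site differs
        a = "GGA" * 30
        b = "GGC" * 30
        res = dnds_ng86(a, b)
        assert res.caution_flag == "dS_too_large"
        assert math.isinf(res.dS)

    def test_min_codons_precondition(self):
        with pytest.raises(ValueError):
            dnds_ng86("TTT", "TTT")

    @pytest.mark.parametrize("omega_true", [0.2, 1.0])
    def test_parameter_recovery(self, omega_true):
        """NG86 recovers the simulated omega on 300-codon pairs."""
        rng = np.random.default_rng(int(omega_true * 10))
        estimates = []
        codons = [c for c in map("".join, itertools.product("ACGT", repeat=3))
                  if str(Seq(c).translate()) != "*"]
        for _ in range(12):
            anc = "".join(rng.choice(codons, size=300))
            evolved = evolve_sequence(
                anc, divergence_my=100, rate=0.002, rng=rng,
                constrained=[(0, len(anc), omega_true)],
            )
            res = dnds_ng86(anc, evolved)
            if res.omega is not None:
                estimates.append(res.omega)
        assert estimates
        assert np.mean(estimates) == pytest.approx(omega_true, abs=0.15)
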