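"""Trio classifier truth tables, compound-het pairing rules, and the
extended-pedigree parent-of-origin consistency check, each validated
against independently written brute-force oracles."""

import itertools

import pytest
from hypothesis import given, strategies as st

from imprintseek.core import (
    ExpressedParent,
    Pedigree,
    PedigreeMember,
    Sex,
    Zygosity,
)
from imprintseek.inheritance import (
    TrioGenotypes,
    classify_de_novo,
    classify_imprinted,
    classify_recessive,
    find_compound_het_pairs,
    pedigree_origin_consistency,
    unambiguous_parent,
)
from imprintseek.simulate import fig1_family_fixture

from conftest import trio_variant

Z = Zygosity
ZS = [Z.HOM_REF, Z.HET, Z.HOM_ALT]
ALL_TRIOS = [TrioGenotypes(*combo) for combo in itertools.product(ZS, repeat=3)]

# independent oracle: decide each mode from alt-allele dosages (0/1/2)
_DOSE = {Z.HOM_REF: 0, Z.HET: 1, Z.HOM_ALT: 2}


def oracle_de_novo(t: TrioGenotypes) -> bool:
    c, m, f = _DOSE[t.child], _DOSE[t.mother], _DOSE[t.father]
    return c == 1 and m == 0 and f == 0


def oracle_recessive(t: TrioGenotypes) -> bool:
    c, m, f = _DOSE[t.child], _DOSE[t.mother], _DOSE[t.father]
    return c == 2 and m == 1 and f == 1


def oracle_imprinted(t: TrioGenotypes, parent: ExpressedParent) -> bool:
    c, m, f = _DOSE[t.child], _DOSE[t.mother], _DOSE[t.father]
    if parent is ExpressedParent.PATERNAL:
        m, f = f, m
    return c >= 1 and m == 1 and f <= 1


class TestTrioClassifierTruthTables:
    def test_de_novo_matches_oracle_over_27_combinations(self):
        accepted = [t for t in ALL_TRIOS if classify_de_novo(t)]
        assert accepted == [t for t in ALL_TRIOS if oracle_de_novo(t)]
        assert len(accepted) == 1
        assert accepted[0] == TrioGenotypes(Z.HET, Z.HOM_REF, Z.HOM_REF)

    def test_de_novo_hom_alt_flag_adds_one_pattern(self):
        accepted = [t for t in ALL_TRIOS if classify_de_novo(t, allow_hom_alt=True)]
        assert len(accepted) == 2
        assert TrioGenotypes(Z.HOM_ALT, Z.HOM_REF, Z.HOM_REF) in accepted

    def test_recessive_matches_oracle_over_27_combinations(self):
        accepted = [t for t in ALL_TRIOS if classify_recessive(t)]
        assert accepted == [t for t in ALL_TRIOS if oracle_recessive(t)]
        assert len(accepted) == 1
        # a hom-alt (affected) parent is excluded at defaults
        assert not classify_recessive(TrioGenotypes(Z.HOM_ALT, Z.HOM_ALT, Z.HET))
        assert classify_recessive(
            TrioGenotypes(Z.HOM_ALT, Z.HOM_ALT, Z.HET), allow_hom_alt_parent=True
        )

    @pytest.mark.parametrize("parent", [ExpressedParent.MATERNAL, ExpressedParent.PATERNAL])
    def test_imprinted_matches_oracle_over_27_combinations(self, parent):
        accepted = [t for t in ALL_TRIOS if classify_imprinted(t, parent)]
        assert accepted == [t for t in ALL_TRIOS if oracle_imprinted(t, parent)]
        assert len(accepted) == 4

    def test_imprinted_examples(self):
        # affected child and carrier mother; father may carry from his father
        assert classify_imprinted(
            TrioGenotypes(Z.HET, Z.HET, Z.HOM_REF), ExpressedParent.MATERNAL
        )
        assert not classify_imprinted(
            TrioGenotypes(Z.HET, Z.HOM_REF, Z.HET), ExpressedParent.MATERNAL
        )
        assert classify_imprinted(
            TrioGenotypes(Z.HET, Z.HOM_REF, Z.HET), ExpressedParent.PATERNAL
        )

    def test_de_novo_disjoint_from_imprinted_modes(self):
        for t in ALL_TRIOS:
            if classify_de_novo(t):
                assert not classify_imprinted(t, ExpressedParent.MATERNAL)
                assert not classify_imprinted(t, ExpressedParent.PATERNAL)

    def test_recessive_imprinted_overlap_is_exactly_one_pattern(self):
        overlap = [
            t
            for t in ALL_TRIOS
            if classify_recessive(t) and classify_imprinted(t, ExpressedParent.MATERNAL)
        ]
        assert overlap == [TrioGenotypes(Z.HOM_ALT, Z.HET, Z.HET)]


def gene_variant(child, mother, father, pos):
    return trio_variant(child, mother, father, pos=pos, gene="GENEX")


class TestCompoundHetPairs:
    TRIO = ("proband", "mother", "father")

    def test_trans_pair_retained(self):
        v1 = gene_variant(Z.HET, Z.HET, Z.HOM_REF, 100)
        v2 = gene_variant(Z.HET, Z.HOM_REF, Z.HET, 200)
        assert find_compound_het_pairs([v1, v2], *self.TRIO) == [(v1, v2)]

    def test_cis_pair_excluded(self):
        v1 = gene_variant(Z.HET, Z.HET, Z.HOM_REF, 100)
        v2 = gene_variant(Z.HET, Z.HET, Z.HOM_REF, 200)
        assert find_compound_het_pairs([v1, v2], *self.TRIO) == []

    def test_homozygous_parent_excluded(self):
        v1 = gene_variant(Z.HET, Z.HOM_REF, Z.HOM_ALT, 100)
        v2 = gene_variant(Z.HET, Z.HET, Z.HOM_REF, 200)
        assert find_compound_het_pairs([v1, v2], *self.TRIO) == []

    def test_ambiguous_pair_retained(self):
        # v1 carried by both parents: cannot be phased, keep the pair
        v1 = gene_variant(Z.HET, Z.HET, Z.HET, 100)
        v2 = gene_variant(Z.HET, Z.HET, Z.HOM_REF, 200)
        assert len(find_compound_het_pairs([v1, v2], *self.TRIO)) == 1

    def test_all_ambiguous_yields_all_pairs(self):
        n = 6
        variants = [gene_variant(Z.HET, Z.HET, Z.HET, 100 * (i + 1)) for i in range(n)]
        pairs = find_compound_het_pairs(variants, *self.TRIO)
        assert len(pairs) == n * (n - 1) // 2

    def test_child_must_be_het(self):
        v1 = gene_variant(Z.HOM_ALT, Z.HET, Z.HET, 100)
        with pytest.raises(ValueError, match="not heterozygous"):
            find_compound_het_pairs([v1], *self.TRIO)

    @given(
        st.lists(
            st.tuples(st.sampled_from(ZS), st.sampled_from([Z.HOM_REF, Z.HET, Z.HOM_ALT])),
            min_size=2,
            max_size=6,
        )
    )
    def test_exclusion_rules_match_pairwise_oracle(self, parent_zygs):
        """No returned pair violates rule (a) cis or (b) homozygous parent;
        oracle re-derives both rules from raw parental carrier states."""
        variants = [
            gene_variant(Z.HET, mz, fz, 100 * (i + 1))
            for i, (mz, fz) in enumerate(parent_zygs)
        ]
        pairs = find_compound_het_pairs(variants, *self.TRIO)
        expected = []
        for v1, v2 in itertools.combinations(variants, 2):
            states = []
            hom_parent = False
            for v in (v1, v2):
                mo = v.genotype("mother").zygosity
                fa = v.genotype("father").zygosity
                hom_parent |= Z.HOM_ALT in (mo, fa)
                mo_c, fa_c = mo is not Z.HOM_REF, fa is not Z.HOM_REF
                if mo_c and not fa_c:
                    states.append("M")
                elif fa_c and not mo_c:
                    states.append("P")
                else:
                    states.append("?")
            cis = states[0] == states[1] and states[0] in ("M", "P")
            if not cis and not hom_parent:
                expected.append((v1, v2))
        assert pairs == expected

    def test_unambiguous_parent_phasing(self):
        v = gene_variant(Z.HET, Z.HET, Z.HOM_REF, 100)
        assert unambiguous_parent(v, "mother", "father") == "maternal"
        v = gene_variant(Z.HET, Z.HOM_REF, Z.HET, 100)
        assert unambiguous_parent(v, "mother", "father") == "paternal"
        v = gene_variant(Z.HET, Z.HET, Z.HET, 100)
        assert unambiguous_parent(v, "mother", "father") is None


# ---------------------------------------------------------------------------
# extended-pedigree origin consistency


def oracle_consistency(pedigree, genotypes, parent):
    """Brute force over all origin assignments, re-deriving the
    transmission and phenotype rules from first principles."""
    members = {m.sample_id: m for m in pedigree.members}
    carriers = sorted(
        s for s, z in genotypes.items() if z in (Z.HET, Z.HOM_ALT)
    )

    def carries(sid):
        if sid is None or sid not in genotypes:
            return None
        return genotypes[sid] is not Z.HOM_REF

    option_sets = []
    for s in carriers:
        if genotypes[s] is Z.HOM_ALT:
            option_sets.append([("mat", "pat")])
        else:
            option_sets.append([("mat",), ("pat",)])
    for combo in itertools.product(*option_sets):
        ok = True
        assignment = dict(zip(carriers, combo))
        for s, sides in assignment.items():
            m = members[s]
            if "mat" in sides and carries(m.mother_id) is False:
                ok = False
            if "pat" in sides and carries(m.father_id) is False:
                ok = False
        if not ok:
            continue
        expressed = "mat" if parent is ExpressedParent.MATERNAL else "pat"
        for s in genotypes:
            mutant_expressed = expressed in assignment.get(s, ())
            if members[s].affected != mutant_expressed:
                ok = False
        if ok:
            return True
    return False


class TestPedigreeOriginConsistency:
    def test_family_fixture_consistent_with_maternal_expression(self):
        ped, genotypes = fig1_family_fixture()
        result = pedigree_origin_consistency(ped, genotypes, ExpressedParent.MATERNAL)
        assert result.consistent
        # witness: proband's mutant allele is maternal, mother's paternal
        assert result.assignment["proband"] == "maternal-allele"
        assert result.assignment["mother"] == "paternal-allele"
        assert result.assignment["aunt"] == "paternal-allele"

    def test_family_fixture_inconsistent_with_paternal_expression(self):
        # the proband's mutant allele must be maternal (father is hom-ref),
        # hence silenced under paternal expression — contradicting affected
        ped, genotypes = fig1_family_fixture()
        result = pedigree_origin_consistency(ped, genotypes, ExpressedParent.PATERNAL)
        assert not result.consistent
        assert result.assignment is None

    def test_no_carriers_is_trivially_consistent(self):
        ped, _ = fig1_family_fixture()
        genotypes = {s: Z.HOM_REF for s in ("mother", "father", "grandmother")}
        # an unaffected family with no carriers imposes no constraints
        result = pedigree_origin_consistency(ped, genotypes, ExpressedParent.MATERNAL)
        assert result.consistent

    def test_hom_alt_child_of_hom_ref_parents_contradiction(self):
        ped, _ = fig1_family_fixture()
        genotypes = {"proband": Z.HOM_ALT, "mother": Z.HOM_REF, "father": Z.HOM_REF}
        result = pedigree_origin_consistency(ped, genotypes, ExpressedParent.MATERNAL)
        assert not result.consistent
        assert "homozygous" in result.diagnostic

    @given(
        st.dictionaries(
            st.sampled_from(
                ["proband", "mother", "father", "grandfather", "grandmother", "aunt"]
            ),
            st.sampled_from(ZS),
            min_size=1,
            max_size=6,
        ),
        st.sampled_from([ExpressedParent.MATERNAL, ExpressedParent.PATERNAL]),
    )
    def test_matches_bruteforce_oracle_on_six_member_family(self, genotypes, parent):
        ped, _ = fig1_family_fixture()
        result = pedigree_origin_consistency(ped, genotypes, parent)
        assert result.consistent == oracle_consistency(ped, genotypes, parent)

    def test_trio_subset_consistent(self):
        ped, full = fig1_family_fixture()
        trio_only = {s: full[s] for s in ("proband", "mother", "father")}
        assert pedigree_origin_consistency(ped, trio_only, ExpressedParent.MATERNAL)
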