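import itertools

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from concavekit.library_design import (
    IUPAC_NUCLEOTIDES,
    STOP,
    CoverageError,
    FilterRule,
    FilterSpec,
    LibraryDesignError,
    apply_design_filters,
    build_library,
    design_degenerate_codon,
    expand_degenerate_codon,
    library_to_tsv,
)


def oracle_expand(triplet):
    """Independent expansion: enumerate bases and translate with biopython."""
    out = {}
    for bases in itertools.product(*(IUPAC_NUCLEOTIDES[c] for c in triplet)):
        aa = str(Seq("".join(bases)).translate())
        out[aa] = out.get(aa, 0) + 1
    return out


class TestExpandDegenerateCodon:
    def test_single_codon(self):
        codon = expand_degenerate_codon("AAA")
        assert dict(codon.encoded_aas) == {"K": 1}
        assert codon.dna_degeneracy == 1

    def test_rac_encodes_asn_asp(self):
        codon = expand_degenerate_codon("RAC")
        assert dict(codon.encoded_aas) == {"N": 1, "D": 1}
        assert codon.dna_degeneracy == 2

    def test_nnk_covers_all_twenty_plus_stop(self):
        codon = expand_degenerate_codon("NNK")
        assert codon.dna_degeneracy == 32
        assert len(codon.distinct_aas) == 20
        assert codon.encoded_aas[STOP] == 1

    @pytest.mark.parametrize("triplet", ["NNK", "NNS", "RAC", "TGG", "VNS", "DBK"])
    def test_matches_independent_translation(self, triplet):
        codon = expand_degenerate_codon(triplet)
        oracle = oracle_expand(triplet)
        assert dict(codon.encoded_aas) == oracle
        assert codon.dna_degeneracy == sum(oracle.values())

    def test_invalid_symbol_rejected(self):
        with pytest.raises(LibraryDesignError):
            expand_degenerate_codon("AXZ")
        with pytest.raises(LibraryDesignError):
            expand_degenerate_codon("AAAA")


class TestDesignDegenerateCodon:
    def test_asn_asp_top_codon_has_no_offtargets(self):
        ranked = design_degenerate_codon({"N", "D"})
        top = ranked[0]
        assert top.triplet == "RAC"
        assert top.distinct_aas == {"N", "D"}

    def test_trp_unique_codon(self):
        ranked = design_degenerate_codon({"W"})
        assert ranked[0].triplet == "TGG"
        assert ranked[0].dna_degeneracy == 1

    def test_all_twenty_with_stop_allowed_prefers_nnk_class(self):
        ranked = design_degenerate_codon(set("ACDEFGHIKLMNPQRSTVWY"), forbid_stop=False)
        top = ranked[0]
        assert len(top.distinct_aas) == 20
        assert top.dna_degeneracy == 32  # NNK/NNS beat degeneracy-64 NNN

    def test_coverage_error_reports_stop_permitting_alternative(self):
        # no stop-free codon covers all 20 amino acids
        with pytest.raises(CoverageError, match="alternative"):
            design_degenerate_codon(set("ACDEFGHIKLMNPQRSTVWY"), forbid_stop=True)

    def test_agrees_with_exhaustive_oracle_on_random_sets(self):
        """Top-ranked codon matches an independent exhaustive enumeration
        under the (off-targets, degeneracy, lexicographic) ordering."""
        rng = np.random.default_rng(7)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        symbols = sorted(IUPAC_NUCLEOTIDES)
        for _ in range(50):
            size = int(rng.integers(1, 9))
            desired = set(rng.choice(aas, size=size, replace=False))
            best = None
            for combo in itertools.product(symbols, repeat=3):
                triplet = "".join(combo)
                enc = oracle_expand(triplet)
                distinct = {a for a in enc if a != STOP}
                if not desired <= distinct or STOP in enc:
                    continue
                key = (len(distinct - desired), sum(enc.values()), triplet)
                if best is None or key < best[0]:
                    best = (key, triplet)
            try:
                ranked = design_degenerate_codon(desired)
                assert best is not None
                assert ranked[0].triplet == best[1]
            except CoverageError:
                assert best is None

    def test_every_ranked_codon_covers_desired(self):
        desired = {"A", "G", "S"}
        for codon in design_degenerate_codon(desired)[:20]:
            assert desired <= codon.distinct_aas


class TestBuildLibrary:
    def test_protein_diversity_is_product(self):
        # three exactly coverable desired sets (RAC, GNC, NTC)
        parent = "NAFW"
        spec = build_library(
            parent,
            {1: {"N", "D"}, 2: {"A", "G", "V", "D"}, 3: {"F", "L", "I", "V"}},
            require_parent=True,
        )
        assert spec.protein_diversity == 2 * 4 * 4
        assert spec.fits_capacity

    def test_twelve_exact_quads_exceed_capacity(self):
        """12 positions x degeneracy-4 codons: 4^12 = 16,777,216 DNA variants
        overflow a 1e7 transformation capacity."""
        parent = "A" * 12
        desired = {p: {"A", "G", "V", "D"} for p in range(1, 13)}  # GBC-codable
        spec = build_library(parent, desired)
        assert spec.dna_diversity == 4**12 == 16_777_216
        assert all(c.dna_degeneracy == 4 for *_, c in spec.positions)
        assert not spec.fits_capacity

    def test_empty_position_list(self):
        spec = build_library("ACD", {})
        assert spec.dna_diversity == spec.protein_diversity == 1
        assert spec.fits_capacity

    def test_parent_residue_required_by_default(self):
        with pytest.raises(LibraryDesignError, match="parent"):
            build_library("W", {1: {"N", "D"}})
        spec = build_library("W", {1: {"N", "D"}}, require_parent=False)
        assert spec.positions[0][3].triplet == "RAC"

    def test_protein_diversity_never_exceeds_dna(self):
        rng = np.random.default_rng(3)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(10):
            size = int(rng.integers(1, 6))
            desired = set(rng.choice(aas, size=size, replace=False))
            parent = rng.choice(sorted(desired))
            spec = build_library(str(parent), {1: desired}, forbid_stop=False)
            assert spec.protein_diversity <= spec.dna_diversity

    def test_tsv_output(self, tmp_path):
        spec = build_library("NW", {1: {"N", "D"}})
        library_to_tsv(spec, tmp_path / "lib.tsv")
        text = (tmp_path / "lib.tsv").read_text()
        assert "RAC" in text and "dna_diversity=2" in text


class TestDesignFilters:
    METRICS = pd.DataFrame(
        {
            "ddg": [-50.0, -30.0, -50.0],
            "contact_molecular_surface": [500.0, 500.0, 300.0],
            "pae": [5.0, 5.0, 5.0],
        }
    )

    def test_single_survivor(self):
        report = apply_design_filters(self.METRICS)
        assert len(report.survivors) == 1
        assert report.attrition == {"ddg": 1, "contact_molecular_surface": 1, "pae": 0}

    def test_empty_table(self):
        report = apply_design_filters(self.METRICS.iloc[0:0])
        assert len(report.survivors) == 0
        assert all(v == 0 for v in report.attrition.values())

    def test_missing_column_is_schema_error(self):
        with pytest.raises(KeyError):
            apply_design_filters(self.METRICS.drop(columns=["pae"]))

    def test_missing_values_fail_and_are_counted(self):
        df = self.METRICS.copy()
        df.loc[0, "pae"] = np.nan
        report = apply_design_filters(df)
        assert len(report.survivors) == 0
        assert report.missing["pae"] == 1

    def test_boundary_rows_pass_but_flagged(self):
        df = pd.DataFrame(
            {"ddg": [-40.0], "contact_molecular_surface": [400.0], "pae": [10.0]}
        )
        report = apply_design_filters(df)
        assert len(report.survivors) == 1
        assert report.boundary == {"ddg": 1, "contact_molecular_surface": 1, "pae": 1}

    def test_survivors_match_brute_force_recount(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(
            {
                "ddg": rng.uniform(-80, 0, 100),
                "contact_molecular_surface": rng.uniform(200, 600, 100),
                "pae": rng.uniform(2, 20, 100),
            }
        )
        report = apply_design_filters(df)
        brute = sum(
            1
            for _, r in df.iterrows()
            if r.ddg <= -40 and r.contact_molecular_surface >= 400 and r.pae <= 10
        )
        assert len(report.survivors) == brute

    def test_survivor_set_order_invariant(self):
        spec_fwd = FilterSpec()
        spec_rev = FilterSpec(rules=list(reversed(FilterSpec().rules)))
        rng = np.random.default_rng(12)
        df = pd.DataFrame(
            {
                "ddg": rng.uniform(-80, 0, 50),
                "contact_molecular_surface": rng.uniform(200, 600, 50),
                "pae": rng.uniform(2, 20, 50),
            }
        )
        fwd = apply_design_filters(df, spec_fwd).survivors.index.tolist()
        rev = apply_design_filters(df, spec_rev).survivors.index.tolist()
        assert fwd == rev

    def test_optional_plddt_rule(self):
        df = pd.DataFrame(
            {
                "ddg": [-50.0, -50.0],
                "contact_molecular_surface": [500.0, 500.0],
                "pae": [5.0, 5.0],
                "plddt": [85.0, 70.0],
            }
        )
        report = apply_design_filters(df, FilterSpec.with_plddt(80.0))
        assert len(report.survivors) == 1


def test_expand_design_duality():
    """Every codon returned for a desired set expands to a superset of it."""
    for desired in ({"N", "D"}, {"W"}, {"A", "V", "I", "L"}):
        for codon in design_degenerate_codon(desired)[:10]:
            assert desired <= expand_degenerate_codon(codon.triplet).distinct_aas
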