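"""Variant notation, masking, motif calls and dataset round trips."""

import numpy as np
import pytest

from mtfounder.haplotype_io import (
    DELETION,
    INSERTION,
    TRANSITION,
    JoinError,
    MitoHaplotype,
    Mutation,
    PositionConfig,
    VariantParseError,
    apply_position_mask,
    assign_haplogroup,
    diff_against_reference,
    parse_profile,
    parse_variant_token,
    polynesian_motif_definitions,
    read_dataset,
    write_metadata,
    write_variant_table,
)
from mtfounder.reference import MT_LENGTH, reference_sequence, transition_partner

from helpers import hap, tsub


class TestParseVariantToken:
    @pytest.mark.parametrize(
        "token, position, allele, kind, index",
        [
            ("16247G", 16247, "G", TRANSITION, None),
            ("16,247 G", 16247, "G", TRANSITION, None),
            ("14022G", 14022, "G", TRANSITION, None),
            ("315.1C", 315, "C", INSERTION, 1),
            ("522d", 522, "d", DELETION, None),
            ("310C", 310, "C", None, None),  # kind depends on reference base
        ],
    )
    def test_grammar(self, token, position, allele, kind, index):
        m = parse_variant_token(token)
        assert (m.position, m.derived_allele, m.insertion_index) == (
            position, allele, index,
        )
        if kind is not None:
            assert m.kind == kind

    def test_transversion_classified(self):
        ref = reference_sequence()
        pos = 5000
        base = ref[pos - 1]
        other = {"A": "C", "C": "A", "G": "T", "T": "G"}[base]
        assert parse_variant_token(f"{pos}{other}").kind == "transversion"

    @pytest.mark.parametrize("token", ["", "G16247", "16247", "16247GG", "12.C"])
    def test_malformed(self, token):
        with pytest.raises(VariantParseError):
            parse_variant_token(token)

    def test_out_of_range(self):
        with pytest.raises(VariantParseError):
            parse_variant_token(f"{MT_LENGTH + 1}G")

    def test_reference_allele_rejected(self):
        ref_base = reference_sequence()[16246]  # A at 16247
        with pytest.raises(VariantParseError):
            parse_variant_token(f"16247{ref_base}")

    def test_token_round_trip(self):
        for t in ["16247G", "315.1C", "522d"]:
            assert parse_variant_token(t).token() == t


class TestPositionMask:
    def test_allele_specific_and_defining_site(self):
        h = MitoHaplotype("s", parse_profile("16519C 14022G"))
        masked = apply_position_mask(h, PositionConfig.default())
        assert {m.token() for m in masked.variants} == {"14022G"}

    def test_empty_profile_passes_through(self):
        h = MitoHaplotype("s", frozenset())
        assert apply_position_mask(h, PositionConfig.default()).variants == frozenset()

    def test_poly_c_stretch_fully_masked(self):
        # 310C excluded explicitly; 312 falls inside the 308-315 range
        h = MitoHaplotype("s", parse_profile("310C 312C"))
        assert apply_position_mask(h, PositionConfig.default()).variants == frozenset()

    def test_placeholder_position_always_excluded(self):
        cfg = PositionConfig.default()
        assert 3107 in cfg.excluded_positions

    def test_masking_idempotent_and_shrinking(self):
        rng = np.random.default_rng(11)
        cfg = PositionConfig.default()
        for _ in range(50):
            positions = rng.choice(
                np.arange(1, MT_LENGTH + 1), size=rng.integers(0, 12), replace=False
            )
            variants = []
            for p in positions:
                if transition_partner(reference_sequence()[p - 1]) is None:
                    continue
                variants.append(tsub(int(p)))
            h = MitoHaplotype("s", frozenset(variants))
            once = apply_position_mask(h, cfg)
            assert len(once.variants) <= len(h.variants)
            assert apply_position_mask(once, cfg).variants == once.variants

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            PositionConfig(default_weight=7, reduced_weight=10)
        with pytest.raises(ValueError):
            PositionConfig(
                downweighted=frozenset({146}), excluded_positions=frozenset({146})
            )

    def test_hotspot_weighting(self):
        cfg = PositionConfig.default()
        assert cfg.weight(16189) == 7.0
        assert cfg.weight(8701) == 10.0
        # a 10x relative rate reproduces the 10 -> 7 down-weighting
        cfg2 = PositionConfig.default()
        cfg2.per_position_rate = {8701: 10.0, 100: 1.0, 200: 1.0}
        assert cfg2.weight(8701) == pytest.approx(7.0)


class TestHaplogroupAssignment:
    def test_motif_calls(self):
        defs = polynesian_motif_definitions()
        full = MitoHaplotype("a", parse_profile("14022G 16247G 73G"))
        assert assign_haplogroup(full, defs) == "B4a1a1a"
        pooled = MitoHaplotype("b", parse_profile("14022G"))
        assert assign_haplogroup(pooled, defs) == "B4a1a1 (PM-combined)"
        assert assign_haplogroup(pooled, defs, mode="strict") == "B4a1a1"
        assert assign_haplogroup(MitoHaplotype("c", frozenset()), defs) == "unassigned"


class TestReadDataset:
    def _write_meta(self, path, sample_ids):
        with open(path, "w") as fh:
            fh.write("sample_id,island,region,lat,lon\n")
            for sid in sample_ids:
                fh.write(f"{sid},Isla,Reg,-3.5,143.2\n")

    def test_fasta_identical_to_reference(self, tmp_path):
        ref = reference_sequence()
        fasta = tmp_path / "seqs.fa"
        fasta.write_text(f">s1\n{ref}\n")
        meta = tmp_path / "meta.csv"
        self._write_meta(meta, ["s1"])
        (h,) = read_dataset(fasta, meta)
        assert h.variants == frozenset()
        assert (h.island, h.region) == ("Isla", "Reg")

    def test_fasta_single_substitution(self, tmp_path):
        ref = list(reference_sequence())
        ref[16246] = "G"  # A -> G at 16247
        fasta = tmp_path / "seqs.fa"
        fasta.write_text(f">s1\n{''.join(ref)}\n")
        meta = tmp_path / "meta.csv"
        self._write_meta(meta, ["s1"])
        (h,) = read_dataset(fasta, meta)
        assert {m.token() for m in h.variants} == {"16247G"}

    def test_ambiguous_bases_are_missing(self):
        seq = list(reference_sequence())
        seq[99] = "N"
        seq[200] = "R"
        assert diff_against_reference("".join(seq)) == frozenset()

    def test_orphan_metadata_is_a_join_error(self, tmp_path):
        table = tmp_path / "haps.tsv"
        table.write_text("s1 16247G\ns2 .\n")
        meta = tmp_path / "meta.csv"
        self._write_meta(meta, ["s1", "s2", "s3"])
        with pytest.raises(JoinError, match="s3"):
            read_dataset(table, meta)

    def test_strict_length_check(self, tmp_path):
        fasta = tmp_path / "seqs.fa"
        fasta.write_text(">s1\nACGT\n")
        meta = tmp_path / "meta.csv"
        self._write_meta(meta, ["s1"])
        with pytest.raises(ValueError, match="length"):
            read_dataset(fasta, meta, strict=True)

    def test_variant_table_round_trip(self, tmp_path):
        haps = [
            hap("a", [1000, 2000], region="R"),
            hap("b", [], region="R"),
            MitoHaplotype("c", parse_profile("315.1C 522d 16247G"), region="R"),
        ]
        seq, meta = tmp_path / "haps.tsv", tmp_path / "meta.csv"
        write_variant_table(haps, seq)
        write_metadata(haps, meta)
        back = {h.sample_id: h.variants for h in read_dataset(seq, meta)}
        for h in haps:
            assert back[h.sample_id] == h.variants

    def test_fasta_and_profile_ingestion_agree(self, tmp_path):
        rng = np.random.default_rng(5)
        ref = list(reference_sequence())
        variants = []
        for p in rng.choice(np.arange(100, 16000), size=6, replace=False):
            p = int(p)
            partner = transition_partner(ref[p - 1])
            if partner is None:
                continue
            variants.append(tsub(p))
            ref[p - 1] = partner
        h = MitoHaplotype("s1", frozenset(variants))
        fasta, table, meta = (tmp_path / n for n in ("f.fa", "t.tsv", "m.csv"))
        fasta.write_text(f">s1\n{''.join(ref)}\n")
        write_variant_table([h], table)
        self._write_meta(meta, ["s1"])
        (via_fasta,) = read_dataset(fasta, meta)
        (via_table,) = read_dataset(table, meta)
        assert via_fasta.variants == via_table.variants

    def test_duplicate_site_rejected(self):
        with pytest.raises(ValueError, match="share"):
            MitoHaplotype(
                "s",
                frozenset(
                    {
                        Mutation(16247, "G", TRANSITION),
                        Mutation(16247, "C", "transversion"),
                    }
                ),
            )
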