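import dataclasses

import pytest

from proteopath import (
    ConfigurationError,
    InputValidationError,
    IntegrityError,
    KnowledgeBase,
    MatchingConfig,
    MatchingType,
    Participant,
    Pathway,
    Proteoform,
    ProteoformParseError,
    Ptm,
    Reaction,
    SyntheticKBConfig,
    alter_proteoform,
    eligible_proteoforms,
    generate_synthetic_kb,
    load_kb,
    parse_proteoform,
    save_kb,
    sensitivity_experiment,
)

from conftest import make_fixture_kb


class TestLoadSave:
    def test_fixture_counts(self, fixture_kb_dir):
        kb = load_kb(fixture_kb_dir)
        assert len(kb.proteoforms) == 12
        assert len(kb.reactions) == 6
        assert len(kb.pathways) == 4

    def test_round_trip_identity(self, fixture_kb, fixture_kb_dir, tmp_path):
        kb = load_kb(fixture_kb_dir)
        assert kb.proteoforms == fixture_kb.proteoforms
        assert kb.reactions == fixture_kb.reactions
        assert kb.pathways == fixture_kb.pathways
        assert kb.gene_map == fixture_kb.gene_map
        assert kb.variant_map == fixture_kb.variant_map
        assert kb.sequences == fixture_kb.sequences
        # file contents stable across a second save
        d2 = tmp_path / "kb2"
        save_kb(kb, d2)
        for f in sorted(fixture_kb_dir.iterdir()):
            assert (d2 / f.name).read_bytes() == f.read_bytes()

    @pytest.mark.parametrize("n_proteins, n_reactions, n_pathways",
                             [(10, 8, 3), (40, 50, 8), (120, 150, 20)])
    def test_round_trip_across_kb_sizes(self, tmp_path, n_proteins,
                                        n_reactions, n_pathways):
        kb = generate_synthetic_kb(
            SyntheticKBConfig(n_proteins=n_proteins, n_reactions=n_reactions,
                              n_pathways=n_pathways),
            seed=31,
        )
        save_kb(kb, tmp_path / "kb")
        back = load_kb(tmp_path / "kb")
        assert back.proteoforms == kb.proteoforms
        assert back.reactions == kb.reactions
        assert back.pathways == kb.pathways

    def test_missing_file_is_configuration_error(self, fixture_kb_dir):
        (fixture_kb_dir / "genes.tsv").unlink()
        with pytest.raises(ConfigurationError, match="genes.tsv"):
            load_kb(fixture_kb_dir)

    def test_unknown_pathway_reference_is_integrity_error(self, fixture_kb_dir):
        with open(fixture_kb_dir / "pathway_reactions.tsv", "a") as fh:
            fh.write("PW99\tR1\n")
        with pytest.raises(IntegrityError, match="PW99"):
            load_kb(fixture_kb_dir)

    def test_unknown_reaction_reference_is_integrity_error(self, fixture_kb_dir):
        with open(fixture_kb_dir / "pathway_reactions.tsv", "a") as fh:
            fh.write("PW1\tR99\n")
        with pytest.raises(IntegrityError, match="R99"):
            load_kb(fixture_kb_dir)

    def test_malformed_proteoform_cell_reports_file_and_line(
        self, fixture_kb_dir
    ):
        with open(fixture_kb_dir / "proteoforms.tsv", "a") as fh:
            fh.write("P10009;00046:0\n")
        with pytest.raises(ProteoformParseError, match="proteoforms.tsv"):
            load_kb(fixture_kb_dir)

    def test_reference_site_sentinel_normalized_to_unknown(
        self, fixture_kb_dir
    ):
        # -1 in a reference cell is legacy notation for an unknown site
        with open(fixture_kb_dir / "proteoforms.tsv", "a") as fh:
            fh.write("P10001;00047:-1\n")
        kb = load_kb(fixture_kb_dir)
        assert Proteoform("P10001", None, (Ptm("00047", None),)) \
            in kb.proteoforms


class TestModelInvariants:
    def test_reaction_requires_participants(self):
        with pytest.raises(InputValidationError):
            Reaction("R1", "empty", ())

    def test_participant_vocabularies_are_closed(self):
        p = Proteoform("P1")
        with pytest.raises(InputValidationError):
            Participant(p, "bystander")
        with pytest.raises(InputValidationError):
            Participant(p, "input", "sidecar:X")
        assert Participant(p, "input", "complex:C1").context == "complex:C1"

    def test_parent_cycle_is_integrity_error(self, fixture_kb):
        pathways = dict(fixture_kb.pathways)
        pathways["PW1"] = dataclasses.replace(pathways["PW1"], parent_id="PW2")
        with pytest.raises(IntegrityError, match="cycle"):
            KnowledgeBase(
                proteoforms=fixture_kb.proteoforms,
                reactions=fixture_kb.reactions,
                pathways=pathways,
                gene_map=fixture_kb.gene_map,
            )

    def test_unlisted_participant_is_integrity_error(self, fixture_kb):
        reactions = dict(fixture_kb.reactions)
        reactions["R9"] = Reaction(
            "R9", "ghost", (Participant(Proteoform("P99999"), "input"),)
        )
        with pytest.raises(IntegrityError, match="P99999"):
            KnowledgeBase(
                proteoforms=fixture_kb.proteoforms,
                reactions=reactions,
                pathways={},
                gene_map=fixture_kb.gene_map,
            )

    def test_hierarchy_navigation(self, fixture_kb):
        assert fixture_kb.ancestors("PW2") == ["PW1"]
        assert fixture_kb.top_level("PW2") == "PW1"
        assert fixture_kb.top_level("PW3") == "PW3"
        assert fixture_kb.reaction_closure("PW1") == ("R1", "R3", "R5", "R6")


class TestGenerator:
    def test_deterministic_files_for_fixed_seed(self, tmp_path):
        config = SyntheticKBConfig(n_proteins=60, n_reactions=80, n_pathways=12)
        for run in ("a", "b"):
            save_kb(generate_synthetic_kb(config, seed=7), tmp_path / run)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_different_seeds_differ(self):
        config = SyntheticKBConfig(n_proteins=40, n_reactions=50, n_pathways=8)
        a = generate_synthetic_kb(config, seed=1)
        b = generate_synthetic_kb(config, seed=2)
        assert a.proteoforms != b.proteoforms

    def test_zero_ptm_fraction_yields_unmodified_references(self):
        kb = generate_synthetic_kb(
            SyntheticKBConfig(n_proteins=50, ptm_fraction=0.0,
                              n_reactions=60, n_pathways=8),
            seed=11,
        )
        assert all(not p.ptms for p in kb.proteoforms)

    def test_every_proteoform_participates(self):
        kb = generate_synthetic_kb(
            SyntheticKBConfig(n_proteins=50, n_reactions=30, n_pathways=8),
            seed=5,
        )
        participating = {
            part.proteoform
            for r in kb.reactions.values()
            for part in r.participants
        }
        assert participating == set(kb.proteoforms)

    def test_ptm_pathway_prevalence_increases_with_ptm_fraction(self):
        def share_with_modified_participant(frac, seed):
            kb = generate_synthetic_kb(
                SyntheticKBConfig(n_proteins=60, ptm_fraction=frac,
                                  n_reactions=40, n_pathways=15),
                seed=seed,
            )
            n = sum(
                any(p.ptms for p in kb.pathway_participants(pid))
                for pid in kb.pathways
            )
            return n / len(kb.pathways)

        seeds = range(4)
        shares = [
            sum(share_with_modified_participant(f, s) for s in seeds) / len(seeds)
            for f in (0.0, 0.3, 0.8)
        ]
        assert shares[0] <= shares[1] <= shares[2]
        assert shares[0] == 0.0

    def test_infeasible_configuration_rejected(self):
        with pytest.raises(ConfigurationError):
            SyntheticKBConfig(participants_per_reaction_range=(2, 1))
        with pytest.raises(ConfigurationError):
            generate_synthetic_kb(
                SyntheticKBConfig(
                    n_proteins=2, ptm_fraction=0.0,
                    participants_per_reaction_range=(2, 50),
                ),
                seed=0,
            )


class TestAlteration:
    def test_single_ptm_rule(self):
        rec = alter_proteoform(parse_proteoform("X1;00046:15"))
        assert str(rec.altered) == "X1;00000:20"
        assert str(rec.original) == "X1;00046:15"

    def test_two_ptm_rule_moves_second_site_too(self):
        rec = alter_proteoform(parse_proteoform("X1;00046:15,00047:30"))
        assert str(rec.altered) == "X1;00000:20,00047:35"

    def test_third_ptm_unchanged(self):
        rec = alter_proteoform(
            parse_proteoform("X1;00046:15,00047:30,00048:60")
        )
        assert str(rec.altered) == "X1;00000:20,00047:35,00048:60"

    def test_requires_at_least_one_ptm(self):
        with pytest.raises(InputValidationError):
            alter_proteoform(parse_proteoform("X1;"))


def controlled_kb(seed=42):
    """Synthetic KB where alteration shifts are the only differences:
    no isoforms, every modified protein has multiple modified forms."""
    return generate_synthetic_kb(
        SyntheticKBConfig(
            n_proteins=120, isoform_fraction=0.0, ptm_fraction=0.7,
            n_reactions=150, n_pathways=20,
        ),
        seed=seed,
    )


class TestSensitivity:
    KB = controlled_kb()

    def _shares(self, margin=5, n_samples=2, sample_size=60):
        df = sensitivity_experiment(
            self.KB, n_samples=n_samples, sample_size=sample_size,
            configs=[MatchingConfig(mt, margin) for mt in MatchingType],
            seed=123,
        )
        return df.groupby("matching_type")[["original_pct", "others_pct"]].mean()

    def test_original_recovery_by_stringency(self):
        shares = self._shares()
        assert shares.loc["one_no_types", "original_pct"] == 100.0
        assert shares.loc["accession", "original_pct"] == 100.0
        assert shares.loc["strict", "original_pct"] == 0.0

    def test_accession_others_full_when_other_forms_exist(self):
        # eligibility guarantees >= 2 modified forms per sampled protein,
        # so another same-accession proteoform always exists
        shares = self._shares()
        assert shares.loc["accession", "others_pct"] == 100.0

    def test_stringency_ordering_of_original_shares(self):
        s = self._shares()["original_pct"]
        no_types = [s["superset_no_types"], s["one_no_types"],
                    s["subset_no_types"]]
        typed = [s["one"], s["subset"]]
        assert all(s["accession"] >= x for x in no_types)
        assert all(min(no_types) >= x for x in typed)
        assert all(x >= s["strict"] for x in typed)

    def test_no_types_at_least_as_sensitive_as_typed(self):
        shares = self._shares()
        for typed, untyped in [("one", "one_no_types"),
                               ("subset", "subset_no_types"),
                               ("superset", "superset_no_types")]:
            for col in ("original_pct", "others_pct"):
                assert shares.loc[typed, col] <= shares.loc[untyped, col]

    def test_sampling_is_seeded_and_without_replacement(self):
        df1 = sensitivity_experiment(self.KB, 1, 40, seed=9)
        df2 = sensitivity_experiment(self.KB, 1, 40, seed=9)
        assert df1.equals(df2)

    def test_insufficient_pool_raises(self, fixture_kb):
        with pytest.raises(ConfigurationError, match="eligible"):
            sensitivity_experiment(fixture_kb, 1, 300, seed=0)


def test_eligibility_filter_requires_multiple_modified_forms():
    kb = make_fixture_kb()
    pool = eligible_proteoforms(kb)
    # only P10001 carries two modified proteoforms in the fixture
    assert {p.accession for p in pool} == {"P10001"}
    assert all(p.ptms for p in pool)
    assert len(pool) == 2
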