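import numpy as np
import pytest

from nanossl.event_io import write_events
from nanossl.synthetic_data import (
    AB42_SEQUENCE,
    DELTA_VOLUME_E22G,
    DELTA_VOLUME_G37R,
    DELTA_VOLUME_PHOSPHO,
    BarcodeSimParams,
    PeptideSimParams,
    barcode_template,
    dataset_from_recipe,
    default_peptide_classes,
    generate_dataset,
    load_volume_table,
    mutate_sequence,
    peptide_template,
    simulate_barcode_event,
    simulate_peptide_event,
    template_oracle_accuracy,
)


class TestBarcodeEvents:
    def test_all_zero_barcode_is_flat_carrier(self):
        params = BarcodeSimParams(noise_sd=0.0)
        ev = simulate_barcode_event("000", params, seed=1)
        np.testing.assert_allclose(ev.trace, params.carrier_level)

    def test_spikes_are_local_to_their_site(self):
        params = BarcodeSimParams(noise_sd=0.0)
        a = barcode_template("101", params, 500)
        b = barcode_template("001", params, 500)
        diff = np.nonzero(a != b)[0]
        assert diff.size == params.spike_width_points
        assert diff.max() - diff.min() == params.spike_width_points - 1
        assert diff.max() < 250  # bit sites live in the first half

    def test_eight_noiseless_templates_are_distinct(self):
        params = BarcodeSimParams(noise_sd=0.0)
        labels = [format(i, "03b") for i in range(8)]
        temps = [barcode_template(b, params, 500) for b in labels]
        for i in range(8):
            for j in range(i + 1, 8):
                assert np.max(np.abs(temps[i] - temps[j])) >= params.spike_amp / 2

    def test_binding_spike_in_latter_half(self):
        params = BarcodeSimParams(noise_sd=0.0)
        bound = barcode_template("000", BarcodeSimParams(noise_sd=0.0, binding_site="bound"), 500)
        unbound = barcode_template("000", params, 500)
        diff = np.nonzero(bound != unbound)[0]
        assert diff.min() > 250

    def test_deterministic_given_seed(self):
        params = BarcodeSimParams()
        a = simulate_barcode_event("110", params, seed=9)
        b = simulate_barcode_event("110", params, seed=9)
        np.testing.assert_array_equal(a.trace, b.trace)

    def test_geometry_violation_rejected(self):
        with pytest.raises(ValueError):
            BarcodeSimParams(spike_width_points=200, event_len_range=(300, 400))


class TestPeptideEvents:
    def test_equal_volume_residues_give_flat_segment(self):
        table = {"A": 0.1, "B": 0.1}
        params = PeptideSimParams(
            sequence="AB", volume_table=table, noise_sd=0.0, out_len=24
        )
        ev = simulate_peptide_event(params, seed=0)
        np.testing.assert_allclose(ev.trace, ev.trace[0])

    def test_mutation_changes_only_its_dwell_window(self):
        wild = PeptideSimParams(noise_sd=0.0)
        mut = PeptideSimParams(sequence=mutate_sequence(AB42_SEQUENCE, 22, "G"), noise_sd=0.0)
        tw, tm = peptide_template(wild), peptide_template(mut)
        diff = np.nonzero(np.abs(tw - tm) > 1e-12)[0]
        # residue 22 occupies raw points [252, 264); resampling keeps it local
        assert diff.size > 0
        assert 240 <= diff.min() and diff.max() <= 275
        # depth change equals depth_per_volume * (vol(E) - vol(G)) at the plateau
        vols = load_volume_table()
        expected = wild.depth_per_volume * (vols["E"] - vols["G"])
        assert np.max(np.abs(tw - tm)) == pytest.approx(expected, rel=1e-9)

    def test_volume_delta_mechanism_matches_published_delta(self):
        wild = PeptideSimParams(noise_sd=0.0)
        ptm = PeptideSimParams(noise_sd=0.0, volume_deltas={26: DELTA_VOLUME_PHOSPHO})
        tw, tp = peptide_template(wild), peptide_template(ptm)
        assert np.max(np.abs(tw - tp)) == pytest.approx(
            wild.depth_per_volume * DELTA_VOLUME_PHOSPHO, rel=1e-9
        )

    def test_ptm_effect_smaller_than_mutations(self):
        """Template perturbation ordering: phosphorylation < E22G < G37R."""
        base = PeptideSimParams(noise_sd=0.0)
        t0 = peptide_template(base)

        def effect(deltas):
            t = peptide_template(PeptideSimParams(noise_sd=0.0, volume_deltas=deltas))
            return np.max(np.abs(t - t0))

        e_ptm = effect({26: DELTA_VOLUME_PHOSPHO})
        e_e22g = effect({22: -DELTA_VOLUME_E22G})
        e_g37r = effect({37: DELTA_VOLUME_G37R})
        assert e_ptm < e_e22g < e_g37r

    def test_same_seed_identical_different_seed_differs(self):
        params = PeptideSimParams()
        a = simulate_peptide_event(params, seed=4)
        b = simulate_peptide_event(params, seed=4)
        c = simulate_peptide_event(params, seed=5)
        np.testing.assert_array_equal(a.trace, b.trace)
        assert not np.array_equal(a.trace, c.trace)

    def test_dwell_mean_matches_parameter(self):
        """Mean per-residue dwell across many events is within 10% of nominal."""
        params = PeptideSimParams(dwell_mean_points=12.0)
        durations = [
            simulate_peptide_event(params, seed=s).duration_points for s in range(1000)
        ]
        mean_dwell = np.mean(durations) / len(AB42_SEQUENCE)
        assert abs(mean_dwell - 12.0) <= 1.2

    def test_missing_volume_entry_errors(self):
        with pytest.raises(ValueError):
            PeptideSimParams(sequence="AXZ", volume_table={"A": 0.1})


class TestMutateSequence:
    def test_reference_positions(self):
        assert AB42_SEQUENCE[21] == "E" and AB42_SEQUENCE[36] == "G"
        assert AB42_SEQUENCE[25] == "S"
        m = mutate_sequence(AB42_SEQUENCE, 37, "R")
        assert m[36] == "R" and m[:36] == AB42_SEQUENCE[:36] and m[37:] == AB42_SEQUENCE[37:]
        assert mutate_sequence(AB42_SEQUENCE, 22, "G")[21] == "G"

    def test_involution(self):
        m = mutate_sequence(AB42_SEQUENCE, 22, "G")
        assert mutate_sequence(m, 22, "E") == AB42_SEQUENCE

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            mutate_sequence(AB42_SEQUENCE, 43, "A")


class TestGenerateDataset:
    def test_barcode8_cardinality(self):
        events, manifest = generate_dataset("barcode8", n_per_class=10, seed=0)
        assert len(events) == 80 and len(events.class_names) == 8
        assert manifest["class_counts"]["000"] == 10

    def test_peptide_three_variant_classes(self):
        events, _ = generate_dataset("peptide", n_per_class=3, seed=0)
        assert events.class_names == ["native", "E22G", "G37R"]
        assert events.fixed_length == 500

    def test_binding_task_labels(self):
        events, _ = generate_dataset("binding2", n_per_class=5, seed=0)
        assert sorted(events.class_names) == ["bound", "unbound"]

    def test_imbalanced_counts(self):
        events, _ = generate_dataset(
            "peptide", n_per_class=4, seed=0, class_counts={"native": 7}
        )
        labels = events.labels()
        assert labels.count("native") == 7 and labels.count("E22G") == 4

    def test_byte_identical_regeneration(self, tmp_path):
        p1, p2 = tmp_path / "a.ndjson", tmp_path / "b.ndjson"
        for p in (p1, p2):
            events, _ = generate_dataset("peptide", n_per_class=4, seed=11)
            write_events(events, p, "ndjson")
        assert p1.read_bytes() == p2.read_bytes()

    def test_recipes_load(self):
        for name, n_classes in [("abeta3-default", 3), ("barcode8-easy", 8),
                                ("binding2-easy", 2)]:
            events, manifest = dataset_from_recipe(name, n_per_class=2)
            assert len(events.class_names) == n_classes
            assert manifest["task"] in ("peptide", "barcode8", "binding2")


class TestTemplateOracle:
    def test_noiseless_events_classified_perfectly(self):
        """Oracle ceiling: nearest template is exact at zero noise."""
        pp = PeptideSimParams(noise_sd=0.0)
        events, _ = generate_dataset("peptide", n_per_class=30, seed=3, peptide_params=pp)
        assert template_oracle_accuracy(events, "peptide", peptide_params=pp) == 1.0
        bp = BarcodeSimParams(noise_sd=0.0)
        events, _ = generate_dataset("barcode8", n_per_class=5, seed=3, barcode_params=bp)
        assert template_oracle_accuracy(events, "barcode8", barcode_params=bp) == 1.0
        events, _ = generate_dataset("binding2", n_per_class=10, seed=3, barcode_params=bp)
        assert template_oracle_accuracy(events, "binding2", barcode_params=bp) == 1.0

    def test_noise_degrades_oracle_monotonically(self):
        """The difficulty knob works: accuracy falls as noise rises."""
        grid = [0.0, 0.15, 0.3, 0.6]
        accs = []
        for noise in grid:
            pp = PeptideSimParams(noise_sd=noise)
            seed_accs = [
                template_oracle_accuracy(
                    generate_dataset("peptide", n_per_class=40, seed=s, peptide_params=pp)[0],
                    "peptide",
                    peptide_params=pp,
                )
                for s in (0, 1, 2)
            ]
            accs.append(np.mean(seed_accs))
        assert all(a >= b - 0.02 for a, b in zip(accs, accs[1:]))  # sampling slack
        assert accs[0] > accs[-1]

    def test_default_class_definitions_cover_named_variants(self):
        defs = default_peptide_classes(PeptideSimParams())
        assert [d[0] for d in defs] == ["native", "E22G", "G37R"]
        assert defs[1][1][21] == "G" and defs[2][1][36] == "R"
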