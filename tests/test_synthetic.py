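"""Synthetic-data generator: determinism, planted ground truth, track model."""

import numpy as np
import pytest

from regulonmap import (
    Placement,
    ValidationError,
    call_peaks,
    generate_genome,
    parse_consensus,
    plant_sites,
    read_truth,
    scan_region,
    score_match,
    simulate_probe_track,
    write_truth,
)
from regulonmap.synthetic import simulate_dataset


class TestGenerateGenome:
    def test_divergent_pair_leaves_expected_spacer(self):
        genome = generate_genome(
            seed=1, length=10000,
            gene_plan=[("g1", 1000, 2000, "-"), ("g2", 2600, 3600, "+")],
        )
        g1, g2 = genome.genes_by_start()
        assert g2.start - g1.end - 1 == 599

    def test_same_seed_reproduces_sequence(self):
        a = generate_genome(seed=1, length=2000)
        b = generate_genome(seed=1, length=2000)
        assert a.sequence == b.sequence
        assert generate_genome(seed=2, length=2000).sequence != a.sequence

    def test_overlapping_genes_rejected_by_name(self):
        with pytest.raises(ValidationError, match="g2"):
            generate_genome(seed=1, length=10000,
                            gene_plan=[("g1", 100, 500, "+"), ("g2", 400, 900, "+")])

    def test_out_of_bounds_gene_rejected(self):
        with pytest.raises(ValidationError, match="g1"):
            generate_genome(seed=1, length=100, gene_plan=[("g1", 50, 150, "+")])


class TestPlantSites:
    def test_zero_mismatch_box_scores_full_marks(self, lldr_box):
        genome = generate_genome(seed=5, length=2000)
        edited, truth = plant_sites(
            genome, lldr_box, [Placement(midpoint=1000, n_boxes=1)], seed=5
        )
        box = truth.sites[0].boxes[0]
        assert score_match(box.sequence, lldr_box) == (14, 14)
        start = box.start
        assert edited.sequence[start - 1 : start + 16] == box.sequence

    def test_two_mismatches_drop_score_to_twelve(self, lldr_box):
        genome = generate_genome(seed=5, length=2000)
        _, truth = plant_sites(
            genome, lldr_box, [Placement(midpoint=1000, n_boxes=1, mismatches=2)],
            seed=5,
        )
        assert score_match(truth.sites[0].boxes[0].sequence, lldr_box) == (12, 14)

    def test_box_pair_recovered_by_scanning(self, lldr_box):
        genome = generate_genome(seed=9, length=3000)
        edited, truth = plant_sites(
            genome, lldr_box, [Placement(midpoint=1500, n_boxes=2)], seed=9
        )
        region_start = 1500 - 250
        region = edited.subsequence(region_start, 1500 + 250)
        matches = scan_region(region, lldr_box, top_k=2)
        got_offsets = sorted(m.offset for m in matches)
        true_offsets = sorted(b.start - region_start for b in truth.sites[0].boxes)
        assert got_offsets == true_offsets
        assert all(m.score == 14 for m in matches)

    def test_too_many_mismatches_rejected(self, lldr_box):
        genome = generate_genome(seed=5, length=2000)
        with pytest.raises(ValidationError, match="informative"):
            plant_sites(genome, lldr_box,
                        [Placement(midpoint=1000, mismatches=15)], seed=5)

    def test_planting_inside_gene_requires_flag(self, lldr_box):
        genome = generate_genome(seed=5, length=2000,
                                 gene_plan=[("g1", 900, 1100, "+")])
        with pytest.raises(ValidationError, match="g1"):
            plant_sites(genome, lldr_box, [Placement(midpoint=1000)], seed=5)
        _, truth = plant_sites(
            genome, lldr_box, [Placement(midpoint=1000, intragenic=True)], seed=5
        )
        assert len(truth.sites) == 1

    def test_placement_outside_genome_rejected(self, lldr_box):
        genome = generate_genome(seed=5, length=2000)
        with pytest.raises(ValidationError, match="outside"):
            plant_sites(genome, lldr_box, [Placement(midpoint=5)], seed=5)


class TestSimulateProbeTrack:
    def test_no_sites_and_no_noise_is_flat_baseline(self, lldr_box):
        genome = generate_genome(seed=2, length=5000)
        _, truth = plant_sites(genome, lldr_box, [], seed=2)
        track = simulate_probe_track(genome, truth, noise_sd=0.0, seed=2)
        assert np.all(track.ratios == 1.0)

    def test_apex_equals_amplitude_at_nearest_probe(self, lldr_box):
        genome = generate_genome(seed=2, length=5000)
        # midpoint on a probe centre (grid: 51, 151, ...)
        edited, truth = plant_sites(
            genome, lldr_box,
            [Placement(midpoint=2551, amplitude=62.9)], seed=2,
        )
        track = simulate_probe_track(edited, truth, noise_sd=0.0, seed=2)
        assert track.ratios.max() == pytest.approx(62.9)
        assert track.positions[int(np.argmax(track.ratios))] == 2551

    def test_subthreshold_amplitude_yields_no_peak(self, lldr_box):
        genome = generate_genome(seed=2, length=5000)
        edited, truth = plant_sites(
            genome, lldr_box, [Placement(midpoint=2551, amplitude=5.0)], seed=2
        )
        track = simulate_probe_track(edited, truth, noise_sd=0.0, seed=2)
        assert call_peaks(track, cutoff=6.0) == []

    def test_baseline_outside_fragment_length_of_sites(self, lldr_box):
        genome = generate_genome(seed=4, length=20000)
        edited, truth = plant_sites(
            genome, lldr_box, [Placement(midpoint=10051, amplitude=20.0)], seed=4
        )
        track = simulate_probe_track(edited, truth, fragment_length=250,
                                     noise_sd=0.0, seed=4)
        far = np.abs(track.positions - 10051) > 250
        assert np.all(track.ratios[far] == 1.0)

    def test_same_seed_gives_identical_track(self, lldr_box):
        genome = generate_genome(seed=3, length=5000)
        edited, truth = plant_sites(genome, lldr_box, [Placement(midpoint=2551)],
                                    seed=3)
        t1 = simulate_probe_track(edited, truth, noise_sd=0.2, seed=7)
        t2 = simulate_probe_track(edited, truth, noise_sd=0.2, seed=7)
        assert t1 == t2
        assert t1 != simulate_probe_track(edited, truth, noise_sd=0.2, seed=8)

    def test_jitter_keeps_probe_order(self, lldr_box):
        genome = generate_genome(seed=3, length=20000)
        _, truth = plant_sites(genome, lldr_box, [], seed=3)
        track = simulate_probe_track(genome, truth, noise_sd=0.0, seed=3, jitter=20)
        assert np.all(np.diff(track.positions) > 0)
        assert track.median_spacing() == pytest.approx(100, abs=5)

    def test_invalid_parameters_rejected(self, lldr_box):
        genome = generate_genome(seed=3, length=5000)
        _, truth = plant_sites(genome, lldr_box, [], seed=3)
        with pytest.raises(ValidationError):
            simulate_probe_track(genome, truth, probe_spacing=0)
        with pytest.raises(ValidationError):
            simulate_probe_track(genome, truth, fragment_length=-1)


def test_truth_table_round_trip(tmp_path, small_dataset):
    _, truth, _ = small_dataset
    path = tmp_path / "truth.tsv"
    write_truth(truth, path)
    assert read_truth(path) == truth


def test_dataset_determinism(small_dataset):
    genome, truth, track = small_dataset
    genome2, truth2, track2 = simulate_dataset(seed=11, n_sites=4, mismatches=0,
                                               amplitude=10.0, noise_sd=0.0)
    assert genome.sequence == genome2.sequence
    assert truth == truth2
    assert track == track2
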