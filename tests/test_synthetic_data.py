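import json

import numpy as np
import pytest

from diffmnase import genomeio
from diffmnase.synthetic_data import (
    Domain,
    GenomeSpec,
    TruthSet,
    build_truth,
    choose_hyper_dyads,
    derive_cleavage_weights,
    emit_truth_bundle,
    generate_genome,
    simulate_fragments,
)


class TestGenomeSpec:
    def test_domains_must_tile(self):
        with pytest.raises(ValueError, match="tile"):
            GenomeSpec(
                chromosomes=[("c", 1000)],
                domains={"c": [Domain(0, 500, 0.5)]},
            )

    def test_gc_bounds_enforced(self):
        with pytest.raises(ValueError, match="gc"):
            Domain(0, 100, 1.0)

    def test_default_domain_fills_chromosome(self):
        spec = GenomeSpec(chromosomes=[("c", 1000)])
        assert spec.domains["c"][0].end == 1000

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError, match="length"):
            GenomeSpec(chromosomes=[("c", 0)])


class TestGenerateGenome:
    def test_gc_concentration(self):
        spec = GenomeSpec(
            chromosomes=[("c", 1_000_000)],
            domains={"c": [Domain(0, 1_000_000, 0.5)]},
            seed=1,
        )
        genome, _ = generate_genome(spec)
        seq = np.frombuffer(genome["c"].encode(), dtype=np.uint8)
        gc = np.isin(seq, [ord("G"), ord("C")]).mean()
        assert abs(gc - 0.5) < 0.005  # binomial concentration at n = 1e6

    def test_near_boundary_gc(self):
        spec = GenomeSpec(
            chromosomes=[("c", 50_000)],
            domains={"c": [Domain(0, 50_000, 0.999)]},
            seed=2,
        )
        genome, _ = generate_genome(spec)
        seq = np.frombuffer(genome["c"].encode(), dtype=np.uint8)
        assert np.isin(seq, [ord("G"), ord("C")]).mean() > 0.99

    def test_determinism(self):
        spec = GenomeSpec(chromosomes=[("c", 10_000)], seed=3)
        g1, d1 = generate_genome(spec)
        g2, d2 = generate_genome(spec)
        assert g1 == g2 and np.array_equal(d1["c"], d2["c"])

    def test_dyad_spacing(self):
        spec = GenomeSpec(chromosomes=[("c", 100_000)], seed=4)
        _, dyads = generate_genome(spec)
        gaps = np.diff(dyads["c"])
        assert abs(gaps.mean() - 180) < 2
        assert gaps.min() > 150

    def test_periodic_positioning_autocorrelation(self, periodic_genome):
        # oracle: lag-10 autocorrelation of the W/W dinucleotide indicator
        # around dyads beats neighbouring lags
        spec, genome, dyads = periodic_genome
        seq = np.frombuffer(genome["chrP"].encode(), dtype=np.uint8)
        is_w = np.isin(seq, [ord("A"), ord("T")])
        ww = (is_w[:-1] & is_w[1:]).astype(float)
        offsets = np.arange(-60, 60)
        prof = np.array(
            [ww[dyads["chrP"][10:-10] + o].mean() for o in offsets]
        )
        prof = prof - prof.mean()
        ac = np.correlate(prof, prof, "full")[prof.size - 1 :]
        assert ac[10] > ac[5] and ac[10] > ac[15]
        assert ac[10] > 0.5 * ac[0] * 0.1


class TestDeriveCleavageWeights:
    def test_neutral_genome_weights(self, small_genome):
        spec, genome, dyads = small_genome
        sm = derive_cleavage_weights(genome, dyads, spec, "low")
        w, nuc = sm.weights["chr1"], sm.is_nucleosome["chr1"]
        assert np.all(w[~nuc] == 10.0)
        assert np.all(w[nuc] == 1.0)  # low condition: no sequence sensitivity
        sm_high = derive_cleavage_weights(genome, dyads, spec, "high")
        wh = sm_high.weights["chr1"][nuc]
        # GC 0.5 genome: only the far AT tail of 150-bp footprints can
        # cross the 0.6 threshold
        assert np.mean(wh == 1.0) > 0.98
        assert set(np.unique(wh)) <= {1.0, 2.0}

    def test_at_rich_nucleosomes_doubled_only_in_high(self):
        spec = GenomeSpec(
            chromosomes=[("c", 100_000)],
            domains={"c": [Domain(0, 100_000, 0.2)]},  # AT fraction 0.8
            seed=5,
        )
        genome, dyads = generate_genome(spec)
        high = derive_cleavage_weights(genome, dyads, spec, "high")
        low = derive_cleavage_weights(genome, dyads, spec, "low")
        nuc = high.is_nucleosome["c"]
        assert np.all(high.weights["c"][nuc] == 2.0)
        assert np.all(low.weights["c"][nuc] == 1.0)

    def test_hyper_site_weight_triple(self, small_genome):
        spec, genome, dyads = small_genome
        target = int(dyads["chr1"][100])
        sm = derive_cleavage_weights(
            genome, dyads, spec, "low", hyper_dyads=[("chr1", target)]
        )
        w = sm.weights["chr1"]
        k = 2 * 100 + 1
        assert w[k] == 4.0  # fragile nucleosome
        assert w[k - 1] == 12.0 and w[k + 1] == 12.0  # flanking linkers

    def test_compaction_scales_linkers(self):
        spec = GenomeSpec(
            chromosomes=[("c", 100_000)],
            domains={"c": [Domain(0, 100_000, 0.5, compaction=0.8)]},
            seed=6,
        )
        genome, dyads = generate_genome(spec)
        sm = derive_cleavage_weights(genome, dyads, spec, "low")
        assert np.all(sm.weights["c"][~sm.is_nucleosome["c"]] == 8.0)

    def test_dyad_outside_chromosome_rejected(self, small_genome):
        spec, genome, _ = small_genome
        with pytest.raises(ValueError, match="outside"):
            derive_cleavage_weights(
                genome, {"chr1": np.array([500_000])}, spec, "low"
            )


class TestSimulateFragments:
    def test_exact_count_and_length_gate(self, small_genome):
        spec, genome, dyads = small_genome
        sm = derive_cleavage_weights(genome, dyads, spec, "low")
        frags = simulate_fragments(sm, genomeio.chrom_sizes(genome), 10_000, seed=1)
        assert len(frags) == 10_000
        lengths = np.array([f.length for f in frags])
        assert lengths.min() >= 145 and lengths.max() <= 195

    def test_di_fragments_in_gate(self, small_genome):
        spec, genome, dyads = small_genome
        sm = derive_cleavage_weights(genome, dyads, spec, "low")
        frags = simulate_fragments(
            sm, genomeio.chrom_sizes(genome), 2_000, seed=2, cls="di"
        )
        lengths = np.array([f.length for f in frags])
        assert len(frags) == 2_000
        assert lengths.min() >= 260 and lengths.max() <= 480

    def test_determinism(self, small_genome):
        spec, genome, dyads = small_genome
        sm = derive_cleavage_weights(genome, dyads, spec, "low")
        a = simulate_fragments(sm, genomeio.chrom_sizes(genome), 1_000, seed=3)
        b = simulate_fragments(sm, genomeio.chrom_sizes(genome), 1_000, seed=3)
        assert a == b

    def test_zero_request_rejected(self, small_genome):
        spec, genome, dyads = small_genome
        sm = derive_cleavage_weights(genome, dyads, spec, "low")
        with pytest.raises(ValueError):
            simulate_fragments(sm, genomeio.chrom_sizes(genome), 0, seed=1)

    def test_hyper_site_local_contrast(self, small_genome):
        # planted site: low:high fragment ratio at the site exceeds flanks
        spec, genome, dyads = small_genome
        target = int(dyads["chr1"][500])
        counts = {}
        for cond in ("low", "high"):
            sm = derive_cleavage_weights(
                genome, dyads, spec, cond, hyper_dyads=[("chr1", target)]
            )
            frags = simulate_fragments(
                sm, genomeio.chrom_sizes(genome), 60_000, seed=4
            )
            mids = np.array([f.midpoint for f in frags])
            counts[cond] = (
                np.sum(np.abs(mids - target) < 90),
                np.sum((np.abs(mids - target) >= 900) & (np.abs(mids - target) < 1800)),
            )
        site_ratio = counts["low"][0] / max(counts["high"][0], 1)
        flank_ratio = counts["low"][1] / max(counts["high"][1], 1)
        assert site_ratio > 2 * flank_ratio

    def test_null_genome_condition_counts_correlate_like_replicates(self, small_genome):
        spec, genome, dyads = small_genome
        sizes = genomeio.chrom_sizes(genome)
        sm_low = derive_cleavage_weights(genome, dyads, spec, "low")
        sm_high = derive_cleavage_weights(genome, dyads, spec, "high")

        def counts_10kb(sm, seed):
            frags = simulate_fragments(sm, sizes, 50_000, seed=seed)
            mids = np.array([f.midpoint for f in frags])
            return np.bincount(mids // 10_000, minlength=20)

        low1 = counts_10kb(sm_low, 10)
        low2 = counts_10kb(sm_low, 20)
        high = counts_10kb(sm_high, 30)
        # replicate oracle: condition log ratios no more dispersed than
        # same-condition replicate log ratios
        sd_cond = np.std(np.log2(low1 / high))
        sd_rep = np.std(np.log2(low1 / low2))
        assert sd_cond <= 1.5 * sd_rep


class TestTruthBundle:
    def test_bundle_files(self, tmp_path):
        spec = GenomeSpec(
            chromosomes=[("c", 200_000)],
            seed=7,
            n_hyper_sites=3,
            cnv_segments=[("c", 0, 50_000, 6.0)],
            masked_intervals=[("c", 100_000, 110_000)],
        )
        genome, site_maps, truth = build_truth(spec)
        paths = emit_truth_bundle(spec, truth, str(tmp_path))
        manifest = json.loads(open(paths["manifest"]).read())
        assert len(manifest["hyper_sites"]) == 3
        assert manifest["cnv_segments"][0][3] == 6.0
        mapp = open(paths["mappability"]).read()
        assert "\t100000\t110000\t0\n" in mapp
        cnv = open(paths["cnv_segments"]).read()
        assert "6.0" in cnv
        hyper = genomeio.read_bed(paths["hyper_sites"])
        assert len(hyper) == 3

    def test_condition_asymmetric_bias_r2(self):
        # regressing high-condition window counts on GC yields much larger
        # R^2 than low-condition counts on the same genome
        from diffmnase.pipeline import biased_genome_spec
        from diffmnase.synthetic_data import build_truth

        spec = biased_genome_spec(seed=9, chrom_len=1_500_000, n_hyper_sites=0,
                                  domain_len=300_000)
        genome, site_maps, _ = build_truth(spec)
        sizes = genomeio.chrom_sizes(genome)
        seq = np.frombuffer(genome["chrS"].encode(), dtype=np.uint8)
        is_gc = np.isin(seq, [ord("G"), ord("C")])
        w = 25_000
        gc = is_gc[: (len(seq) // w) * w].reshape(-1, w).mean(axis=1)

        def window_counts(cond, seed):
            frags = simulate_fragments(site_maps[cond], sizes, 150_000, seed=seed)
            mids = np.array([f.midpoint for f in frags])
            return np.bincount(mids // w, minlength=gc.size)[: gc.size]

        r2_high = np.corrcoef(gc, window_counts("high", 1))[0, 1] ** 2
        r2_low = np.corrcoef(gc, window_counts("low", 2))[0, 1] ** 2
        assert r2_high > 0.5
        assert r2_low < 0.2
        assert r2_high > r2_low + 0.3

    def test_hyper_sites_within_chromosomes(self):
        spec = GenomeSpec(chromosomes=[("c", 300_000)], seed=8, n_hyper_sites=5)
        _, _, truth = build_truth(spec)
        for chrom, start, end in truth.hyper_sites:
            assert 0 <= start < end <= 300_000


class TestChooseHyperDyads:
    def test_minimum_separation(self, small_genome):
        _, _, dyads = small_genome
        rng = np.random.default_rng(0)
        chosen = choose_hyper_dyads(dyads, 20, rng, min_sep=2000)
        pos = sorted(p for _, p in chosen)
        assert len(chosen) == 20
        assert min(np.diff(pos)) >= 2000

    def test_too_many_requested(self, small_genome):
        _, _, dyads = small_genome
        with pytest.raises(ValueError):
            choose_hyper_dyads(dyads, 10_000, np.random.default_rng(0))
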