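"""Toy genome construction, event planting, and library simulation."""

import numpy as np
import pytest

from dpnseq.config import SimConfig
from dpnseq.simulate import (
    EventPlan,
    PlantingError,
    _eligible_fragments,
    generate_contaminants,
    generate_genome,
    plant_events,
    simulate_library,
)
from dpnseq.util import digest, gatc_positions, revcomp

CFG = SimConfig(seed=1, n_reads=800)


@pytest.fixture(scope="module")
def genome():
    return generate_genome(CFG)


@pytest.fixture(scope="module")
def planted(genome):
    return plant_events(genome, EventPlan(), seed=1)


def test_genome_structure(genome):
    assert len(genome.chromosomes) >= 2
    n_multi = sum(1 for g in genome.genes if len(g.exons) > 1)
    n_single = sum(1 for g in genome.genes if len(g.exons) == 1)
    assert n_multi >= 2 and n_single >= 1
    genome.validate()  # exons in bounds, sorted; introns canonical


def test_genome_deterministic(genome):
    again = generate_genome(SimConfig(seed=1, n_reads=800))
    assert again.chromosomes == genome.chromosomes
    assert again.genes == genome.genes


def test_pseudogene_pair(genome):
    assert genome.pseudogene_pairs
    parent_id, pseudo_id = genome.pseudogene_pairs[0]
    pseudo = genome.gene(pseudo_id)
    assert pseudo.is_pseudogene and len(pseudo.exons) == 1  # intronless
    ptx = genome.transcript(parent_id)
    ptx_pseudo = genome.transcript(pseudo_id)
    assert len(ptx) == len(ptx_pseudo)
    ident = sum(a == b for a, b in zip(ptx, ptx_pseudo)) / len(ptx)
    assert ident >= 0.95


def test_plant_nothing_is_identity(genome):
    g2, truth = plant_events(genome, EventPlan.none(), seed=1)
    assert truth.is_empty()
    assert g2.chromosomes == genome.chromosomes


def test_planted_fusion_junction_construction(planted):
    """Microhomology bases equal both genomic continuations; non-templated
    bases match neither; junctions carry no GATC."""
    genome, truth = planted
    for fu in truth.fusions:
        seq_a = genome.chromosomes[fu.chrom_a].upper()
        seq_b = genome.chromosomes[fu.chrom_b].upper()
        j = fu.junction
        if fu.mh_len:
            mh = fu.tx_seq[j : j + fu.mh_len]
            assert mh == seq_a[fu.pos_a : fu.pos_a + fu.mh_len]
            assert mh == seq_b[fu.pos_b : fu.pos_b + fu.mh_len]
        if fu.nt_seq:
            assert fu.tx_seq[j : j + len(fu.nt_seq)] == fu.nt_seq
            assert fu.nt_seq[0] != seq_a[fu.pos_a]
            assert fu.nt_seq[-1] != seq_b[fu.pos_b - 1]
        for p in gatc_positions(fu.tx_seq):
            assert p == 0 or not (j - 8 <= p <= j + fu.mh_len + len(fu.nt_seq) + 4)


def test_planted_inclusion_recoverable(planted):
    """The inclusion exon sits inside an annotated intron with canonical new
    splice sites on the coding strand."""
    genome, truth = planted
    incl = [i for i in truth.isoforms if i.category == "exon_inclusion_both_flanks"]
    assert incl
    for iso in incl:
        gene = genome.gene(iso.gene_id)
        es, ee = iso.coords
        assert any(s <= es and ee <= e for s, e in gene.introns())
        seq = genome.chromosomes[iso.chrom].upper()
        if iso.strand == "+":
            assert seq[es - 2 : es] == "AG" and seq[ee : ee + 2] == "GT"
        else:
            assert seq[es - 2 : es] == "AC" and seq[ee : ee + 2] == "CT"


def test_overlapping_explicit_plants_rejected(genome):
    pos = genome.genes[0].exons[0][0] + 20
    chrom = genome.genes[0].chrom
    alt = "A" if genome.chromosomes[chrom][pos].upper() != "A" else "C"
    plan = EventPlan.none()
    plan.explicit_snps = ((chrom, pos, alt), (chrom, pos + 3, alt))
    with pytest.raises(PlantingError):
        plant_events(genome, plan, seed=1)


@pytest.fixture(scope="module")
def sims(planted):
    genome, truth = planted
    cont = generate_contaminants(CFG)
    return genome, truth, {
        s: simulate_library(genome, truth, s, CFG, cont) for s in CFG.barcodes
    }


class TestSimulateLibrary:
    def test_fixed_seed_byte_identical(self, planted):
        genome, truth = planted
        a = simulate_library(genome, truth, "HB4a", CFG)
        b = simulate_library(genome, truth, "HB4a", CFG)
        assert [(r.read_id, r.sequence, r.qualities) for r in a.reads] == [
            (r.read_id, r.sequence, r.qualities) for r in b.reads
        ]

    def test_read_layout_adapter_tag_gatc(self, sims):
        genome, truth, res = sims
        for sample, tag in CFG.barcodes.items():
            n = 0
            for r in res[sample].reads:
                entry = res[sample].log[r.read_id]
                if entry.adapter != "full":
                    continue
                assert r.sequence.startswith(CFG.adapter + tag + "GATC")
                n += 1
            assert n > 500

    def test_error_free_inserts_match_a_transcript(self, sims):
        """At error rate 0 every non-artifact, non-contaminant insert is an
        exact substring of its source transcript."""
        from dpnseq.simulate import _unit_sequences

        genome, truth, res = sims
        for sample in ("HB4a",):
            units = _unit_sequences(genome, truth, sample)
            checked = 0
            for r in res[sample].reads:
                e = res[sample].log[r.read_id]
                if e.kind in ("artifact", "contaminant"):
                    continue
                insert = r.sequence
                if e.adapter == "full":
                    insert = insert[len(CFG.adapter) + 4 :]
                elif e.adapter == "truncated":
                    insert = insert[14:]
                assert any(insert in hseq for hseq, _ in units[e.origin]), r.read_id
                checked += 1
            assert checked > 500

    def test_artifact_reads_have_gatc_at_join(self, sims):
        genome, truth, res = sims
        reads_by_id = {r.read_id: r for sim in res.values() for r in sim.reads}
        n_art = 0
        for sample, sim in res.items():
            for rid, e in sim.log.items():
                if e.kind != "artifact":
                    continue
                n_art += 1
                seq = reads_by_id[rid].sequence
                if e.adapter == "full":
                    insert = seq[len(CFG.adapter) + 4 :]
                elif e.adapter == "truncated":
                    insert = seq[14:]
                else:
                    insert = seq
                j = e.artifact_junction
                if j is not None and j + 4 <= len(insert):
                    assert insert[j : j + 4] == "GATC"
        expected = 2 * round(CFG.n_reads * CFG.artifact_fraction)
        assert n_art == expected

    def test_digestion_conservation(self):
        tx = "AAATTT" + "GATC" + "C" * 30 + "GATC" + "G" * 50
        frags = digest(tx)
        assert "".join(tx[a:b] for a, b in frags) == tx
        assert all(tx[a : a + 4] == "GATC" for a, b in frags[1:])

    def test_size_window_respected(self, planted):
        genome, truth = planted
        for g in genome.genes:
            if g.is_pseudogene:
                continue
            tx = genome.transcript(g.gene_id)
            for a, b in _eligible_fragments(tx, CFG.size_window):
                assert CFG.size_window[0] <= b - a <= CFG.size_window[1]

    def test_expression_profile_chisquare(self, planted):
        """Sampled per-unit read counts follow the configured profile
        (chi-square goodness of fit, p > 0.001 at n = 10,000)."""
        from collections import Counter

        from scipy import stats

        from dpnseq.simulate import default_profiles

        genome, truth = planted
        cfg = SimConfig(seed=5, n_reads=10000, artifact_fraction=0.0,
                        contaminant_fraction=0.0)
        res = simulate_library(genome, truth, "HB4a", cfg)
        counts = Counter(e.origin for e in res.log.values())
        prof = default_profiles(genome, truth)["HB4a"]
        units = [u for u in prof if u in counts or prof[u] > 1e-4]
        exp = np.array([prof[u] for u in units])
        exp = exp / exp.sum() * cfg.n_reads
        obs = np.array([counts.get(u, 0) for u in units], dtype=float)
        keep = exp >= 5
        stat, p = stats.chisquare(obs[keep], exp[keep] * obs[keep].sum() / exp[keep].sum())
        assert p > 0.001
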