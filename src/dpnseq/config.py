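"""Pipeline and simulation configuration.

All thresholds the filtering stages use live in :class:`PipelineConfig`;
everything the read simulator needs lives in :class:`SimConfig`. Both
round-trip through YAML so a whole run is reproducible from one file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Forward PCR primer of the library protocol; reads begin with it.
DEFAULT_ADAPTER = "GAGCAGGTGACCACTC"

#: 4-nt Y-adapter tags: the bases between the GATC overhang and the common
#: adapter arm that differ between the two samples' ligation primers.
DEFAULT_BARCODES = {"HB4a": "TCCC", "C5.2": "CCCT"}


@dataclass
class PipelineConfig:
    """Thresholds for every filtering/classification stage."""

    # read-level quality
    quality_floor: int = 20

    # contaminant screen (rRNA / mitochondrial surrogate database)
    contaminant_max_evalue: float = 1e-20
    contaminant_min_identity: float = 0.85
    contaminant_min_coverage: float = 0.90

    # genome-alignment partition
    complete_min_coverage: float = 0.70
    complete_min_identity: float = 0.96
    partial_min_coverage: float = 0.20
    partial_max_coverage: float = 0.80
    partial_min_identity: float = 0.999
    near_top: float = 0.005
    min_match_floor: int = 20
    max_intron: int = 5000

    # transcript-database alignment (RefSeq stand-in)
    txdb_max_evalue: float = 1e-15
    txdb_min_identity: float = 0.96
    txdb_min_coverage: float = 0.90

    # splice-event / novel-gene discovery
    min_intron_gap: int = 50
    novel_gene_min_distance: int = 8000
    novel_cluster_gap: int = 100
    retention_min_overlap: int = 20
    min_anchor: int = 8
    allow_gc_donor: bool = False

    # SNP calling (dimension set from the study; numeric defaults are ours)
    snp_min_depth: int = 4
    snp_min_alt_ratio: float = 0.25
    snp_min_boundary_dist: int = 5
    snp_end_margin: int = 5
    snp_window: int = 50
    homopolymer_min_run: int = 5
    snp_hom_ratio: float = 0.8

    # fusion detection
    fusion_min_segment: int = 20
    fusion_min_joint_coverage: float = 0.90
    fusion_gatc_margin: int = 4
    support_flank: int = 10
    support_min_identity: float = 0.95

    # differential expression
    dge_fold_cutoff: float = 2.0  # on log2 scale
    ber_prior: tuple[float, float] = (1.0, 1.0)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ber_prior"] = list(self.ber_prior)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "ber_prior" in d:
            d["ber_prior"] = tuple(d["ber_prior"])
        return cls(**d)


@dataclass
class SimConfig:
    """Everything the simulator needs to emit one run's reads.

    ``expression`` maps sample -> {unit id -> fraction of the library}; units
    are genes, planted isoforms, novel genes and fusion transcripts. Unset
    fractions are filled uniformly over the remaining annotated genes.
    """

    seed: int = 1
    n_reads: int = 20000  # per sample
    error_rate: float = 0.0
    read_cap_mean: float = 420.0
    read_cap_sd: float = 60.0
    size_window: tuple[int, int] = (150, 600)
    adapter: str = DEFAULT_ADAPTER
    barcodes: dict = field(default_factory=lambda: dict(DEFAULT_BARCODES))
    artifact_fraction: float = 0.01
    contaminant_fraction: float = 0.055
    adapterless_fraction: float = 0.033
    adapter_truncated_fraction: float = 0.05
    expression: dict | None = None

    # toy-genome layout
    chrom_lengths: tuple[int, ...] = (140000, 90000)
    n_genes: int = 38
    desert: tuple[str, int, int] = ("chr2", 46000, 90000)  # gene-free region

    def __post_init__(self) -> None:
        lo, hi = self.size_window
        if not lo < hi:
            raise ValueError("size window min must be < max")
        tags = list(self.barcodes.values())
        if len(set(tags)) != len(tags):
            raise ValueError("barcode tags must be distinct")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["size_window"] = list(self.size_window)
        d["chrom_lengths"] = list(self.chrom_lengths)
        d["desert"] = list(self.desert)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for k in ("size_window", "chrom_lengths", "desert"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
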