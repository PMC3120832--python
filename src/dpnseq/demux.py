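"""Barcode demultiplexing and initial read filters.

A barcode assignment is valid when the 4-nt tag is flanked by the 5'
adapter sequence and the 3' DpnII restriction site (GATC). Two stringencies
are exposed: ``strict`` (exact full adapter prefix; used for the
between-sample comparative analyses) and ``lenient`` (any recognizable
adapter suffix with at most one mismatch; used for the pooled qualitative
analyses where adapterless reads are the only exclusion). Trimming removes
the adapter and tag but keeps the GATC on the insert.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import Aligner
from .config import PipelineConfig

LENIENT_SUFFIX = 8  # adapter suffix length checked in lenient mode


@dataclass
class Read:
    """A sequenced read with its demultiplexing state."""

    read_id: str
    sequence: str
    qualities: str
    assigned_sample: str | None = None
    trimmed_sequence: str | None = None
    trimmed_qualities: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"{self.read_id}: quality/sequence length mismatch")

    @property
    def insert(self) -> str:
        return self.trimmed_sequence if self.trimmed_sequence is not None else self.sequence


def _check_map(barcode_map: dict[str, str]) -> None:
    tags = list(barcode_map.values())
    if len(set(tags)) != len(tags):
        raise ValueError("barcode tags must be distinct")


def assign_barcode(
    read: Read, mode: str, barcode_map: dict[str, str], adapter: str
) -> str | None:
    """Assign a read to a sample; trims through the tag on success.

    Strict mode: exact adapter prefix + exact tag + GATC. Lenient mode: the
    tag+GATC may follow any position preceded by the adapter's terminal
    ``LENIENT_SUFFIX`` bases with at most one mismatch. Returns the sample id
    or None (read left untrimmed).
    """
    _check_map(barcode_map)
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown demux mode {mode!r}")
    seq = read.sequence
    tag_len = len(next(iter(barcode_map.values())))
    by_tag = {tag: sample for sample, tag in barcode_map.items()}

    if mode == "strict":
        la = len(adapter)
        if seq.startswith(adapter):
            tag = seq[la : la + tag_len]
            if tag in by_tag and seq[la + tag_len : la + tag_len + 4] == "GATC":
                cut = la + tag_len
                read.assigned_sample = by_tag[tag]
                read.trimmed_sequence = seq[cut:]
                read.trimmed_qualities = read.qualities[cut:]
                return read.assigned_sample
        read.assigned_sample = None
        return None

    suffix = adapter[-LENIENT_SUFFIX:]
    for pos in range(LENIENT_SUFFIX, len(seq) - tag_len - 4 + 1):
        tag = seq[pos : pos + tag_len]
        if tag not in by_tag or seq[pos + tag_len : pos + tag_len + 4] != "GATC":
            continue
        window = seq[pos - LENIENT_SUFFIX : pos]
        mism = sum(1 for a, b in zip(window, suffix) if a != b)
        if mism <= 1:
            cut = pos + tag_len
            read.assigned_sample = by_tag[tag]
            read.trimmed_sequence = seq[cut:]
            read.trimmed_qualities = read.qualities[cut:]
            return read.assigned_sample
    read.assigned_sample = None
    return None


def contaminant_screen(
    read: Read,
    contaminant_db: dict[str, str],
    config: PipelineConfig,
    aligner: Aligner | None = None,
) -> str:
    """'drop' iff the best local hit to any contaminant simultaneously meets
    the E-value, identity and coverage thresholds; 'keep' otherwise."""
    if not contaminant_db:
        raise ValueError("contaminant database is empty")
    seq = read.insert
    if not seq:
        return "drop"  # reason: empty
    if aligner is None:
        aligner = Aligner(contaminant_db)
    for rec in aligner.align(read.read_id, seq):
        if (
            rec.evalue(aligner.db_len) <= config.contaminant_max_evalue
            and rec.identity >= config.contaminant_min_identity
            and rec.coverage >= config.contaminant_min_coverage
        ):
            return "drop"
    return "keep"


@dataclass
class FlowAccounting:
    """Ordered per-stage read accounting; percentages are always recomputed
    from the stored counts."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)  # (name, input, retained)

    def add(self, name: str, n_input: int, n_retained: int) -> None:
        if not 0 <= n_retained <= n_input:
            raise ValueError(f"stage {name}: retained {n_retained} not within input {n_input}")
        self.stages.append((name, n_input, n_retained))

    def dropped(self, name: str) -> int:
        for n, i, r in self.stages:
            if n == name:
                return i - r
        raise KeyError(name)

    def as_rows(self) -> list[dict]:
        from .report import percent

        return [
            {
                "stage": n,
                "input": i,
                "retained": r,
                "dropped": i - r,
                "percent_retained": percent(r, i, 1) if i else 0.0,
            }
            for n, i, r in self.stages
        ]


def run_demux(
    reads: list[Read],
    barcode_map: dict[str, str],
    adapter: str,
    contaminant_db: dict[str, str],
    config: PipelineConfig,
) -> tuple[dict[str, str | None], dict[str, str | None], FlowAccounting]:
    """Initial filters: contaminant screen then adapter/tag demux.

    Returns (lenient assignment, strict assignment, accounting). A read is
    retained iff it survives the contaminant screen and has a lenient-mode
    barcode assignment; the strict assignment is a subset used downstream for
    the comparative analyses.
    """
    aligner = Aligner(contaminant_db)
    lenient: dict[str, str | None] = {}
    strict: dict[str, str | None] = {}
    n_contam = 0
    n_no_adapter = 0
    for read in reads:
        sample = assign_barcode(read, "lenient", barcode_map, adapter)
        if contaminant_screen(read, contaminant_db, config, aligner) == "drop":
            n_contam += 1
            lenient[read.read_id] = None
            strict[read.read_id] = None
            continue
        lenient[read.read_id] = sample
        if sample is None:
            n_no_adapter += 1
            strict[read.read_id] = None
            continue
        # strict re-check on the untrimmed sequence
        strict_read = Read(read.read_id, read.sequence, read.qualities)
        strict[read.read_id] = assign_barcode(strict_read, "strict", barcode_map, adapter)
    total = len(reads)
    acct = FlowAccounting()
    acct.add("contaminant_screen", total, total - n_contam)
    acct.add("adapter_tag", total - n_contam, total - n_contam - n_no_adapter)
    return lenient, strict, acct
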