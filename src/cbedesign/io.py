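"""Sequence readers and guide-report writers.

Inputs are plain-text ORFs (the whole file minus whitespace, lowercase
accepted) or FASTA via biopython; outputs are TSV (one guide per row, with
a ``#``-prefixed header recording tool version, PAM, window and seed) or
JSON mirroring the full report structure. Coordinates in all outputs are
1-based inclusive on the forward strand of the input.
"""

from __future__ import annotations

import csv
import io as _io
import json
import sys
from dataclasses import dataclass, asdict
from pathlib import Path

from Bio import SeqIO

from . import __version__
from .guide_design import EditingWindow, GuideReport
from .seqcore import OpenReadingFrame, SequenceError, normalize

__all__ = [
    "RunConfig",
    "read_sequence",
    "read_orf",
    "write_guides",
    "read_guides",
    "report_row",
    "report_to_dict",
]

TSV_COLUMNS = (
    "protospacer", "pam", "strand", "start", "end",
    "edited_C_distances", "primary_change", "outcome_class", "bystanders", "score",
)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run, recorded in every output header."""

    pam: str = "NGG"
    window: tuple[int, int] = (13, 19)
    mode: str = "stops"
    output_format: str = "tsv"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        EditingWindow(*self.window)  # validates bounds
        if self.output_format not in ("tsv", "json"):
            raise SequenceError(f"unknown output format {self.output_format!r}")

    def header(self) -> dict:
        return {
            "tool": "cbedesign",
            "version": __version__,
            "pam": self.pam,
            "window": f"{self.window[0]}-{self.window[1]}",
            "mode": self.mode,
            "seed": self.seed,
            "coordinates": "1-based inclusive, forward strand of input",
        }


def _sniff_fasta(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return line.lstrip().startswith(">")
    raise SequenceError(f"{path}: empty file")


def read_sequence(path: str | Path, fmt: str | None = None,
                  record: str | None = None) -> str:
    """Read a normalized sequence from plain text or FASTA.

    With a multi-record FASTA, *record* selects the record id; omitting it
    is an error that lists the available ids.
    """
    path = Path(path)
    if not path.exists():
        raise SequenceError(f"no such file: {path}")
    if fmt is None:
        fmt = "fasta" if path.suffix.lower() in (".fa", ".fasta", ".fna") or _sniff_fasta(path) else "txt"
    if fmt == "txt":
        return normalize(path.read_text())
    if fmt != "fasta":
        raise SequenceError(f"unknown format {fmt!r}; expected 'fasta' or 'txt'")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"{path}: no FASTA records")
    if record is not None:
        for rec in records:
            if rec.id == record:
                return normalize(str(rec.seq))
        raise SequenceError(
            f"{path}: record {record!r} not found; ids: {', '.join(r.id for r in records)}"
        )
    if len(records) > 1:
        raise SequenceError(
            f"{path}: {len(records)} records; pick one with --record from: "
            + ", ".join(r.id for r in records)
        )
    return normalize(str(records[0].seq))


def read_orf(path: str | Path, fmt: str | None = None,
             record: str | None = None) -> OpenReadingFrame:
    return OpenReadingFrame(read_sequence(path, fmt=fmt, record=record))


def report_row(report: GuideReport) -> dict:
    """Flat, typed row used for the TSV serialization."""
    return {
        "protospacer": report.site.protospacer,
        "pam": report.site.pam,
        "strand": report.site.strand,
        "start": report.site.start,
        "end": report.site.end,
        "edited_C_distances": ",".join(str(c.d) for c in report.editable),
        "primary_change": report.primary_change,
        "outcome_class": report.primary_outcome.outcome_class,
        "bystanders": ";".join(
            f"d{b.d}:{b.outcome_class}"
            + (f"({b.protein_change})" if b.protein_change else "")
            for b in report.bystanders
        ),
        "score": round(report.score, 4),
    }


def report_to_dict(report: GuideReport) -> dict:
    """Full nested report for the JSON serialization."""
    return {
        "site": asdict(report.site),
        "editable": [asdict(c) for c in report.editable],
        "target_codon": report.target_codon,
        "primary_change": report.primary_change,
        "primary_outcome": {
            "edited_distances": list(report.primary_outcome.edited_distances),
            "codon_changes": [asdict(ch) for ch in report.primary_outcome.codon_changes],
            "outcome_class": report.primary_outcome.outcome_class,
            "truncation_codon": report.primary_outcome.truncation_codon,
        },
        "bystanders": [asdict(b) for b in report.bystanders],
        "score": round(report.score, 4),
    }


def _open_out(dest):
    if dest in (None, "-"):
        return sys.stdout, False
    if isinstance(dest, (str, Path)):
        return open(dest, "w", newline=""), True
    return dest, False


def write_guides(reports: list[GuideReport], dest=None, fmt: str = "tsv",
                 config: RunConfig | None = None) -> None:
    """Serialize guide reports as TSV or JSON to a path, handle, or stdout."""
    config = config or RunConfig(output_format=fmt)
    handle, close = _open_out(dest)
    try:
        if fmt == "tsv":
            for k, v in config.header().items():
                handle.write(f"# {k}={v}\n")
            writer = csv.DictWriter(handle, fieldnames=TSV_COLUMNS, delimiter="\t",
                                    lineterminator="\n")
            writer.writeheader()
            for r in reports:
                writer.writerow(report_row(r))
        elif fmt == "json":
            json.dump(
                {"header": config.header(),
                 "guides": [report_to_dict(r) for r in reports]},
                handle, indent=2,
            )
            handle.write("\n")
        else:
            raise SequenceError(f"unknown output format {fmt!r}")
    finally:
        if close:
            handle.close()


_TYPED = {"start": int, "end": int, "score": float}


def read_guides(path: str | Path) -> tuple[dict, list[dict]]:
    """Parse a file written by :func:`write_guides`; returns (header, rows).

    TSV rows come back with start/end as int and score as float so a
    round trip reproduces :func:`report_row`; JSON returns the full nested
    dicts of :func:`report_to_dict`.
    """
    text = Path(path).read_text()
    if text.lstrip().startswith("{"):
        doc = json.loads(text)
        return doc["header"], doc["guides"]
    header: dict = {}
    body: list[str] = []
    for line in text.splitlines():
        if line.startswith("# "):
            k, _, v = line[2:].partition("=")
            header[k] = v
        else:
            body.append(line)
    rows = []
    for row in csv.DictReader(_io.StringIO("\n".join(body)), delimiter="\t"):
        rows.append({k: _TYPED.get(k, str)(v) for k, v in row.items()})
    return header, rows
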