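"""Readers and writers for the plain-text formats used throughout.

Conventions: all genomic intervals are 0-based half-open, in every file
read or written.  Probe annotation travels as BED6+4 (chrom, start, end,
name, score, strand, category, control_origin, gene_id, region; missing
optional fields are ``.``); sequences come from FASTA keyed by probe id
or a two-column TSV.  Intensities, adjusted intensities, calibration
fits, and curves are TSV.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_probes",
    "write_probes",
    "read_fasta",
    "write_fasta",
    "read_intensities",
    "read_chips",
    "read_dg",
    "write_manifest",
    "sha256_file",
]

_BED_COLS = [
    "chromosome",
    "start",
    "end",
    "probe_id",
    "score",
    "strand",
    "category",
    "control_origin",
    "gene_id",
    "region",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file → ordered mapping of record id to uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def _read_sequences(path: str | Path) -> dict[str, str]:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(">"):
        return read_fasta(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "sequence"} <= set(df.columns):
        raise ValueError(
            f"{path}: sequence TSV must have columns probe_id and sequence"
        )
    return dict(zip(df["probe_id"], df["sequence"].str.upper()))


def read_probes(bed_path: str | Path, seq_path: str | Path) -> pd.DataFrame:
    """Join probe BED annotation with probe sequences.

    Every BED record must have a sequence (and vice versa), and the BED
    span length must equal the sequence length.  Returns the probe
    table with columns ``probe_id, sequence, chromosome, start,
    category, control_origin, gene_id, region``.
    """
    rows = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise ValueError(
                    f"{bed_path}: malformed BED line {lineno}: expected ≥7 fields, got {len(parts)}"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{bed_path}: malformed BED line {lineno}: non-integer coordinates"
                ) from exc
            if start < 0 or end < start:
                raise ValueError(
                    f"{bed_path}: malformed BED line {lineno}: bad span [{start}, {end})"
                )
            parts = parts + ["."] * (len(_BED_COLS) - len(parts))
            rec = dict(zip(_BED_COLS, parts))
            rec["start"], rec["end"] = start, end
            rows.append(rec)
    bed = pd.DataFrame(rows, columns=_BED_COLS).replace({".": None})
    if bed["probe_id"].duplicated().any():
        dup = bed.loc[bed["probe_id"].duplicated(), "probe_id"].head(10)
        raise ValueError(f"{bed_path}: duplicate probe ids: {list(dup)}")
    bad_ctrl = bed[(bed["category"] == "control") & bed["gene_id"].notna()]
    if len(bad_ctrl):
        raise ValueError(
            "control probes may not carry a gene_id: "
            + ", ".join(bad_ctrl["probe_id"].head(10))
        )
    seqs = _read_sequences(seq_path)
    missing = [p for p in bed["probe_id"] if p not in seqs]
    extra = sorted(set(seqs) - set(bed["probe_id"]))
    if missing or extra:
        raise ValueError(
            f"probe id mismatch between BED and sequences; "
            f"first offenders without sequence: {missing[:10]}, "
            f"without BED record: {extra[:10]}"
        )
    bed["sequence"] = bed["probe_id"].map(seqs)
    bad_len = bed[(bed["end"] - bed["start"]) != bed["sequence"].str.len()]
    if len(bad_len):
        raise ValueError(
            "BED span does not match sequence length for probe(s): "
            + ", ".join(bad_len["probe_id"].head(10))
        )
    return bed[
        [
            "probe_id",
            "sequence",
            "chromosome",
            "start",
            "category",
            "control_origin",
            "gene_id",
            "region",
        ]
    ]


def write_probes(probes: pd.DataFrame, bed_path: str | Path, seq_path: str | Path) -> None:
    """Inverse of :func:`read_probes` (sequences go to a TSV)."""
    out = pd.DataFrame(
        {
            "chromosome": probes["chromosome"],
            "start": probes["start"],
            "end": probes["start"] + probes["sequence"].str.len(),
            "probe_id": probes["probe_id"],
            "score": 0,
            "strand": "+",
            "category": probes["category"],
            "control_origin": probes["control_origin"].fillna("."),
            "gene_id": probes["gene_id"].fillna("."),
            "region": probes["region"].fillna("."),
        }
    )
    out.to_csv(bed_path, sep="\t", header=False, index=False)
    probes[["probe_id", "sequence"]].to_csv(seq_path, sep="\t", index=False)


def read_intensities(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chip_id": str})
    need = {"probe_id", "chip_id", "intensity"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: intensity TSV must have columns {sorted(need)}")
    return df


def read_chips(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chip_id": str, "species": str})
    need = {"chip_id", "species"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: chip TSV must have columns {sorted(need)}")
    return df


def read_dg(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    if not {"probe_id", "dg37"} <= set(df.columns):
        raise ValueError(f"{path}: ΔG TSV must have columns probe_id and dg37")
    return df.set_index("probe_id")["dg37"].astype(float)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    params: dict,
    inputs: Mapping[str, str | Path],
    outputs: Mapping[str, str | Path],
) -> None:
    """Run manifest: parameters, package version, input checksums, outputs."""
    from . import __version__

    manifest = {
        "package": "xspecnorm",
        "version": __version__,
        "python": sys.version.split()[0],
        "parameters": params,
        "inputs": {
            name: {"path": str(p), "sha256": sha256_file(p)}
            for name, p in inputs.items()
        },
        "outputs": {name: str(p) for name, p in outputs.items()},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
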