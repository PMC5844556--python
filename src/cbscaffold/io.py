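"""File formats: FASTA sequences, binding-constant tables, barcode TSV,
truth tables and placement reports."""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .cbtheory import Barcode, SequenceRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_constants_table",
    "default_netropsin_table",
    "synthetic_netropsin_constants",
    "read_barcode_tsv",
    "write_barcode_tsv",
    "read_truth_tsv",
    "write_truth_tsv",
]


def read_fasta(path, circular: bool = False) -> list[SequenceRecord]:
    """Read a multi-record FASTA. A record is flagged circular when the
    argument says so or its description contains the word 'circular'."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        circ = circular or "circular" in rec.description.lower()
        records.append(
            SequenceRecord(id=rec.id, bases=str(rec.seq).upper(), circular=circ)
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records, path) -> None:
    bio = [
        BioSeqRecord(
            Seq(r.bases),
            id=r.id,
            description="circular" if r.circular else "linear",
        )
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_constants_table(path) -> dict[str, float]:
    """Read a plain-text binding-constant table: one '4MER<TAB>constant'
    per line, '#' comments."""
    table: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"malformed constants line: {line!r}")
        table[parts[0].upper()] = float(parts[1])
    if not table:
        raise ValueError(f"empty binding-constant table {path}")
    return table


def synthetic_netropsin_constants(seed: int = 20180309) -> dict[str, float]:
    """Synthetic netropsin binding-constant table (1/uM), AT-content graded.

    Netropsin is a minor-groove binder with strong AT preference: constants
    rise roughly geometrically with the AT count of the 4-mer, with a bonus
    when both central positions are A/T, plus deterministic lognormal
    scatter per strand-symmetric 4-mer class. This is a stand-in table with
    realistic magnitudes (0.1-100 /uM); replace it with a measured table
    for real experiments.
    """
    rng = np.random.default_rng(seed)
    comp = str.maketrans("ACGT", "TGCA")
    bases = "ACGT"
    kmers = [a + b + c + d for a in bases for b in bases for c in bases for d in bases]
    table: dict[str, float] = {}
    for kmer in sorted(kmers):
        rc = kmer.translate(comp)[::-1]
        if rc < kmer:
            continue  # one draw per symmetric class
        at = sum(1 for b in kmer if b in "AT")
        k = 0.1 * 10 ** (0.75 * at)
        if kmer[1] in "AT" and kmer[2] in "AT":
            k *= 1.5
        k *= float(rng.lognormal(0.0, 0.25))
        table[kmer] = k
        table[rc] = k
    return table


def default_netropsin_table() -> dict[str, float]:
    """The bundled synthetic netropsin constants (see
    :func:`synthetic_netropsin_constants`)."""
    ref = resources.files("cbscaffold").joinpath("data/netropsin_constants.tsv")
    with resources.as_file(ref) as path:
        return read_constants_table(path)


def write_barcode_tsv(barcode: Barcode, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# bp_per_px={barcode.bp_per_px}\n")
        fh.write(f"# psf_sigma_bp={barcode.psf_sigma_bp}\n")
        fh.write(f"# circular={'true' if barcode.circular else 'false'}\n")
        fh.write("intensity\n")
        for v in barcode.values:
            fh.write(f"{v:.10g}\n")


def read_barcode_tsv(path) -> Barcode:
    meta = {"bp_per_px": 500.0, "psf_sigma_bp": 0.0, "circular": "false"}
    values = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition("=")
            meta[key.strip()] = val.strip()
            continue
        if line == "intensity":
            continue
        values.append(float(line))
    return Barcode(
        values=np.array(values),
        bp_per_px=float(meta["bp_per_px"]),
        psf_sigma_bp=float(meta["psf_sigma_bp"]),
        circular=str(meta["circular"]).lower() in ("true", "1", "yes"),
    )


def write_truth_tsv(truth: dict, path) -> None:
    rows = []
    for contig_id, entry in truth.items():
        rows.append(
            {
                "contig_id": contig_id,
                "start_bp": entry.start_bp,
                "start_px": entry.start_px,
                "orientation": entry.orientation,
                "provenance": entry.provenance,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json_report(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)
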