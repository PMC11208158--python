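"""File I/O: FASTA, TSV, JSON reports and provenance records.

FASTA has no topology field, so circularity is declared per-run via flags or
config rather than in the sequence files.  JSON report schemas carry a
``schema_version`` field; breaking changes bump it.
"""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .covariation import CovariationResult, PairedAlignment
from .recombine import RecombinationProducts
from .substrate import ScanHit

SCHEMA_VERSION = 1

try:
    _VERSION = version("bridgekit")
except PackageNotFoundError:  # pragma: no cover - running from a source tree
    _VERSION = "unknown"


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs; raises FileNotFoundError on a missing path."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def write_scan_tsv(path: str | Path, hits: list[ScanHit]) -> None:
    lines = ["window_start\tstrand\tcore\tverdict"]
    lines += [
        f"{h.window_start}\t{h.strand}\t{h.core}\t{h.report.verdict.value}" for h in hits
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_signed_tsv(path: str | Path, result: CovariationResult) -> None:
    """Signed covariation matrix as TSV (rows: DNA columns, cols: bRNA columns)."""
    n_dna, n_rna = result.signed.shape
    header = "dna_col\t" + "\t".join(str(j + 1) for j in range(n_rna))
    lines = [header]
    for i in range(n_dna):
        lines.append(
            f"{i + 1}\t" + "\t".join(f"{x:.6f}" for x in result.signed[i])
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_json(path: str | Path, payload: dict) -> None:
    payload = {"schema_version": SCHEMA_VERSION, **payload}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def provenance(command: str, inputs: dict, seed: int | None, config: dict) -> dict:
    """A JSON-able record of what a run saw: inputs, seed, version, config."""
    return {
        "command": command,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "seed": seed,
        "config": config,
        "version": _VERSION,
    }


def read_paired_alignment(dna_path: str | Path, rna_path: str | Path) -> PairedAlignment:
    """Two aligned-FASTA blocks, record order paired; gap columns are masked."""
    dna = read_fasta(dna_path)
    rna = read_fasta(rna_path)
    if len(dna) != len(rna):
        raise ValueError(
            f"record count mismatch: {len(dna)} DNA vs {len(rna)} bRNA records"
        )
    return PairedAlignment.from_records([s for _, s in dna], [s for _, s in rna])


def product_features(products: RecombinationProducts) -> list[str]:
    """GFF3-style feature lines marking junctions and heteroduplex positions."""
    lines = ["##gff-version 3"]
    for mol in products.molecules:
        for pos in sorted(mol.heteroduplex):
            lines.append(
                f"{mol.name}\tbridgekit\theteroduplex\t{pos}\t{pos}\t.\t+\t.\t"
                f"Note=top/bottom from different parents"
            )
    for j in (products.junction_a, products.junction_b):
        flags = ",".join(str(i) for i in sorted(j.heteroduplex)) or "none"
        lines.append(
            f"junction-{j.name}\tbridgekit\trecombination_junction\t1\t14\t.\t+\t.\t"
            f"Note=heteroduplex_positions={flags}"
        )
    return lines
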