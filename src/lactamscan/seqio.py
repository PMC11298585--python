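"""Sequence and cluster I/O.

Reads protein FASTA files and the cluster descriptor dialect used by the
mining pipeline (JSON or TSV with columns ``cluster_id, gene_id, sequence,
annotation``), and writes the tabular screening reports.

The amino-acid alphabet is restricted to the 20 standard residues plus ``X``.
The ambiguity codes ``B``, ``Z`` and ``U`` are mapped to ``X`` with a warning
so that substitution-matrix lookups stay total; any other character is
rejected with its position.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
ALPHABET = STANDARD_AA | {"X"}
_REMAP = {"B": "X", "Z": "X", "U": "X"}

ROLE_TAGS = ("nrps", "sulfotransferase", "other", "unknown")

# annotation keywords that pre-fill the gene role tag
_ROLE_KEYWORDS = (
    ("sulfotransferase", "sulfotransferase"),
    ("nonribosomal peptide synthetase", "nrps"),
    ("peptide synthetase", "nrps"),
    ("nrps", "nrps"),
)


def clean_sequence(seq: str, where: str = "sequence") -> str:
    """Uppercase, strip whitespace, map B/Z/U to X, reject anything else."""
    out = []
    mapped = []
    pos = 0
    for ch in seq:
        if ch.isspace():
            continue
        pos += 1
        ch = ch.upper()
        if ch in _REMAP:
            mapped.append((pos, ch))
            ch = _REMAP[ch]
        if ch not in ALPHABET:
            raise ValueError(
                f"illegal residue {ch!r} at position {pos} in {where}"
            )
        out.append(ch)
    if not out:
        raise ValueError(f"empty sequence in {where}")
    if mapped:
        warnings.warn(
            f"{where}: ambiguous residues mapped to X at positions "
            f"{[p for p, _ in mapped]}",
            stacklevel=2,
        )
    return "".join(out)


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Gene:
    gene_id: str
    protein: ProteinRecord
    annotation: str = ""
    role: str = "unknown"

    def __post_init__(self):
        if self.role not in ROLE_TAGS:
            raise ValueError(f"unknown role tag {self.role!r}")


@dataclass(frozen=True)
class ClusterRecord:
    cluster_id: str
    genes: tuple[Gene, ...]

    def __post_init__(self):
        if not self.genes:
            raise ValueError("cluster must contain at least one gene")
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate gene_id in cluster {self.cluster_id}")

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def infer_role(annotation: str) -> str:
    low = annotation.lower()
    for key, role in _ROLE_KEYWORDS:
        if key in low:
            return role
    return "unknown"


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (multi-record) protein FASTA file.

    Raises ``ValueError`` on an empty file, duplicate ids, or illegal
    residues (reported with their position).
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = clean_sequence(str(rec.seq), where=f"{path}:{rec.id}")
        records.append(
            ProteinRecord(id=rec.id, sequence=seq, description=rec.description)
        )
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            header = f"{rec.id} {desc}".strip()
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# cluster descriptors
# ---------------------------------------------------------------------------

def _build_cluster(cluster_id: str, rows: Sequence[dict]) -> ClusterRecord:
    genes = []
    for row in rows:
        gid = str(row["gene_id"])
        seq = row.get("sequence")
        if not seq or (isinstance(seq, float)):
            raise ValueError(f"gene {gid}: missing sequence")
        annotation = str(row.get("annotation") or "")
        role = row.get("role") or infer_role(annotation)
        protein = ProteinRecord(
            id=gid,
            sequence=clean_sequence(str(seq), where=f"gene {gid}"),
            description=annotation,
        )
        genes.append(Gene(gene_id=gid, protein=protein, annotation=annotation, role=role))
    return ClusterRecord(cluster_id=cluster_id, genes=tuple(genes))


def read_cluster(path: str | Path) -> ClusterRecord:
    """Read a cluster descriptor (JSON or TSV).

    JSON dialect::

        {"cluster_id": "bgc1",
         "genes": [{"gene_id": "g1", "sequence": "MK...", "annotation": "..."}]}

    TSV dialect: header ``cluster_id  gene_id  sequence  annotation`` with the
    cluster_id repeated on every row. Role tags are pre-filled from annotation
    keywords (e.g. "sulfotransferase") and default to ``unknown``.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json" or text.lstrip().startswith("{"):
        data = json.loads(text)
        return _build_cluster(str(data["cluster_id"]), data["genes"])
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cluster_id", "gene_id", "sequence"}
    if not required.issubset(df.columns):
        raise ValueError(f"cluster TSV needs columns {sorted(required)}")
    cluster_ids = df["cluster_id"].unique()
    if len(cluster_ids) != 1:
        raise ValueError("cluster TSV must describe exactly one cluster")
    return _build_cluster(str(cluster_ids[0]), df.to_dict("records"))


def write_cluster(cluster: ClusterRecord, path: str | Path) -> None:
    """Write a cluster descriptor; format chosen by suffix (.json or .tsv)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = {
            "cluster_id": cluster.cluster_id,
            "genes": [
                {
                    "gene_id": g.gene_id,
                    "sequence": g.protein.sequence,
                    "annotation": g.annotation,
                    "role": g.role,
                }
                for g in cluster.genes
            ],
        }
        path.write_text(json.dumps(data, indent=1) + "\n")
    else:
        df = pd.DataFrame(
            {
                "cluster_id": cluster.cluster_id,
                "gene_id": g.gene_id,
                "sequence": g.protein.sequence,
                "annotation": g.annotation,
                "role": g.role,
            }
            for g in cluster.genes
        )
        df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# screening reports
# ---------------------------------------------------------------------------

REPORT_CRITERIA = ("triad_motif", "cationic_site", "dap_code", "sulfotransferase")


def write_report(verdicts: Sequence, tsv_path: str | Path,
                 json_path: str | Path | None = None) -> None:
    """Write cluster verdicts as TSV (one row per cluster) and JSON.

    ``verdicts`` are :class:`lactamscan.te_classifier.ClusterVerdict` objects
    (anything exposing ``to_dict``). An empty list yields a header-only TSV.
    """
    dicts = [v.to_dict() for v in verdicts]
    columns = ["cluster_id", "call", "n_passed", "te_gene_id", "a_gene_id"]
    for crit in REPORT_CRITERIA:
        columns += [crit, f"{crit}_evidence"]
    rows = []
    for d in dicts:
        row = {k: d.get(k) for k in ("cluster_id", "call", "n_passed",
                                     "te_gene_id", "a_gene_id")}
        for crit in REPORT_CRITERIA:
            cr = d["criteria"].get(crit, {})
            row[crit] = bool(cr.get("passed", False))
            row[f"{crit}_evidence"] = cr.get("evidence", "")
        rows.append(row)
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(
            json.dumps(dicts, indent=1, sort_keys=True) + "\n"
        )


def read_report_json(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())
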