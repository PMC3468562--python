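"""Reading and writing aligned COI barcode data and derived artifacts.

The on-disk formats are the field's plain-text standards: aligned FASTA for
sequences, TSV for per-specimen metadata, PHYLIP-square or TSV for distance
matrices and Newick for trees.  FASTA headers follow the dialect
``Genus_species|accession|site`` so that raw GenBank downloads can be
relabeled from a metadata table without editing the FASTA itself.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "BarcodeRecord",
    "BarcodeAlignment",
    "read_aligned_fasta",
    "write_aligned_fasta",
    "attach_metadata",
    "read_metadata",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_newick",
    "read_newick",
]

#: Characters accepted in an aligned nucleotide sequence (IUPAC + gap).
VALID_CHARS = set("ACGTURYSWKMBDHVN-.")


@dataclass(frozen=True)
class BarcodeRecord:
    """One aligned COI barcode sequence with its specimen labels.

    ``species`` is the binomial (trinomials are allowed for subspecies, e.g.
    ``Culex pipiens pallens``); ``genus`` defaults to the first name token.
    """

    seq_id: str
    sequence: str
    species: str = ""
    genus: str = ""
    site: str = ""
    accession: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.seq_id!r} has an empty sequence")
        if not self.genus and self.species:
            object.__setattr__(self, "genus", self.species.split()[0])

    @property
    def degapped(self) -> str:
        return self.sequence.replace("-", "").replace(".", "")

    def binomial(self) -> str:
        """Species collapsed to its first two name tokens."""
        toks = self.species.split()
        return " ".join(toks[:2]) if toks else ""


@dataclass
class BarcodeAlignment:
    """An ordered collection of equal-length BarcodeRecords.

    ``frame_offset`` is the 0-based column index of the first codon position
    (coordinates are reported 1-based to users, kept 0-based internally).
    """

    records: list[BarcodeRecord]
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment has no records")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError(f"frame_offset must be 0..2, got {self.frame_offset}")
        length = len(self.records[0].sequence)
        for rec in self.records:
            if len(rec.sequence) != length:
                raise ValueError(
                    f"unaligned input: record {rec.seq_id!r} has length "
                    f"{len(rec.sequence)}, expected {length}"
                )
        ids = [r.seq_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate seq_id(s): {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0].sequence)

    @property
    def seq_ids(self) -> list[str]:
        return [r.seq_id for r in self.records]

    def get(self, seq_id: str) -> BarcodeRecord:
        for r in self.records:
            if r.seq_id == seq_id:
                return r
        raise KeyError(seq_id)

    def species_of(self, collapse_subspecies: bool = False) -> dict[str, str]:
        """seq_id -> species map (optionally trinomials collapsed)."""
        return {
            r.seq_id: (r.binomial() if collapse_subspecies else r.species)
            for r in self.records
        }

    def genus_of(self) -> dict[str, str]:
        return {r.seq_id: r.genus for r in self.records}

    def subset(self, seq_ids: Iterable[str]) -> "BarcodeAlignment":
        wanted = set(seq_ids)
        kept = [r for r in self.records if r.seq_id in wanted]
        return BarcodeAlignment(kept, frame_offset=self.frame_offset)

    def matrix(self) -> np.ndarray:
        """Alignment as an (n, L) array of single characters."""
        return np.array([list(r.sequence) for r in self.records], dtype="U1")


def _parse_header(header: str) -> dict[str, str]:
    """Parse the ``Genus_species|accession|site`` header dialect.

    Missing trailing fields are tolerated; a bare header becomes the seq_id
    with no taxonomy attached.
    """
    parts = header.split("|")
    name = parts[0].replace("_", " ").strip()
    accession = parts[1].strip() if len(parts) > 1 else ""
    site = parts[2].strip() if len(parts) > 2 else ""
    species = name if " " in name else ""
    return {"species": species, "accession": accession, "site": site}


def read_aligned_fasta(path: str | Path, frame_offset: int = 0) -> BarcodeAlignment:
    """Read an aligned FASTA of barcode fragments.

    Sequences are upper-cased; all must share one length or a ValueError
    naming the offending record is raised.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description.split()[0] if rec.description else rec.id
        meta = _parse_header(header)
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_CHARS
        if bad:
            raise ValueError(
                f"record {header!r} contains non-nucleotide characters {sorted(bad)}"
            )
        records.append(
            BarcodeRecord(
                seq_id=header,
                sequence=seq,
                species=meta["species"],
                site=meta["site"],
                accession=meta["accession"],
            )
        )
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return BarcodeAlignment(records, frame_offset=frame_offset)


def write_aligned_fasta(aln: BarcodeAlignment, path: str | Path) -> None:
    """Write the alignment back out in the same header dialect."""
    out = []
    for r in aln.records:
        if r.species or r.accession or r.site:
            header = "|".join(
                [r.species.replace(" ", "_") or r.seq_id.split("|")[0],
                 r.accession, r.site]
            ).rstrip("|")
        else:
            header = r.seq_id
        out.append(SeqRecord(Seq(r.sequence), id=header, description=""))
    SeqIO.write(out, str(path), "fasta")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Metadata TSV with columns seq_id, accession, species, genus, site."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return df


def attach_metadata(
    aln: BarcodeAlignment, table: pd.DataFrame
) -> tuple[BarcodeAlignment, list[str]]:
    """Override species/genus/site from a metadata table.

    Rows are matched by ``seq_id`` first, then by ``accession``.  Returns the
    relabeled alignment and the list of table keys that matched no record
    (also emitted as a warning).
    """
    by_id: dict[str, pd.Series] = {}
    by_acc: dict[str, pd.Series] = {}
    for _, row in table.iterrows():
        sid = str(row.get("seq_id", "") or "")
        acc = str(row.get("accession", "") or "")
        if sid:
            if sid in by_id:
                raise ValueError(f"metadata has duplicate seq_id {sid!r}")
            by_id[sid] = row
        elif acc:
            if acc in by_acc:
                raise ValueError(f"metadata has duplicate accession {acc!r}")
            by_acc[acc] = row

    matched: set[str] = set()
    new_records = []
    for rec in aln.records:
        row = by_id.get(rec.seq_id)
        key = rec.seq_id
        if row is None and rec.accession:
            row = by_acc.get(rec.accession)
            key = rec.accession
        if row is None:
            new_records.append(rec)
            continue
        matched.add(key)
        updates = {}
        for fld in ("species", "genus", "site", "accession"):
            val = str(row.get(fld, "") or "")
            if val:
                updates[fld] = val
        if "species" in updates and "genus" not in updates:
            updates["genus"] = updates["species"].split()[0]
        new_records.append(replace(rec, **updates))

    unmatched = sorted((set(by_id) | set(by_acc)) - matched)
    if unmatched:
        warnings.warn(f"metadata rows matched no record: {unmatched}")
    return BarcodeAlignment(new_records, frame_offset=aln.frame_offset), unmatched


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

def _sanitize_label(label: str) -> str:
    clean = re.sub(r"\s+", "_", label)
    if clean != label:
        warnings.warn(f"label {label!r} contains whitespace; written as {clean!r}")
    return clean


def write_distance_matrix(m, path: str | Path, dialect: str = "phylip") -> None:
    """Write a DistanceMatrix as PHYLIP square or TSV.

    Undefined (saturated) entries are written as ``nan`` and survive a
    round-trip.
    """
    labels = [_sanitize_label(l) for l in m.labels]
    n = len(labels)
    if dialect == "phylip":
        with open(path, "w") as fh:
            fh.write(f"{n}\n")
            for i, lab in enumerate(labels):
                row = " ".join(f"{m.values[i, j]:.10f}" for j in range(n))
                fh.write(f"{lab}  {row}\n")
    elif dialect == "tsv":
        df = pd.DataFrame(m.values, index=labels, columns=labels)
        df.to_csv(path, sep="\t", float_format="%.10f")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_distance_matrix(path: str | Path, dialect: str = "phylip", kind: str = "k2p_total"):
    from .distances import DistanceMatrix

    if dialect == "phylip":
        with open(path) as fh:
            n = int(fh.readline().split()[0])
            labels, rows = [], []
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                labels.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        values = np.asarray(rows, dtype=float)
        if values.shape != (n, n):
            raise ValueError(f"PHYLIP matrix shape {values.shape} != ({n},{n})")
    elif dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        labels = [str(x) for x in df.index]
        values = df.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return DistanceMatrix(labels=labels, values=values, kind=kind)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def write_newick(tree, path: str | Path) -> None:
    """Serialize a Tree (bootstrap supports as internal-node labels)."""
    Path(path).write_text(tree.to_newick() + "\n")


def read_newick(path: str | Path):
    from .nj_tree import Tree

    return Tree.from_newick(Path(path).read_text())
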