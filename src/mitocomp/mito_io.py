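"""Reading, writing and coordinate handling for annotated mitogenomes.

The central record is :class:`AnnotatedMitogenome`: a circular nucleotide
sequence (deposited J-strand) plus an ordered list of strand-aware gene
features. Coordinates follow the GenBank convention — 1-based, inclusive —
and a feature whose ``end`` is smaller than its ``start`` wraps across the
origin of the circle.

Gene names are normalized through an editable synonym table shipped with the
package (``data/gene_synonyms.tsv``), so that COI/COX1/cox1 all become
``cox1``, 16S becomes ``rrnL`` and so on.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from ._codes import revcomp

Kind = Literal["PCG", "tRNA", "rRNA", "control_region"]

#: map amino-acid 3-letter code in "tRNA-Xxx" products to trn labels
_AA_TO_TRN = {
    "Ala": "trnA", "Arg": "trnR", "Asn": "trnN", "Asp": "trnD",
    "Cys": "trnC", "Gln": "trnQ", "Glu": "trnE", "Gly": "trnG",
    "His": "trnH", "Ile": "trnI", "Lys": "trnK", "Met": "trnM",
    "Phe": "trnF", "Pro": "trnP", "Thr": "trnT", "Trp": "trnW",
    "Tyr": "trnY", "Val": "trnV",
}

_FEATURE_KEY = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                "control_region": "D-loop"}
_KEY_TO_KIND = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                "D-loop": "control_region", "misc_feature": "control_region"}


def _load_synonyms() -> dict[str, tuple[str, str]]:
    table = {}
    path = resources.files("mitocomp").joinpath("data/gene_synonyms.tsv")
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            table[row["alias"].upper()] = (row["name"], row["kind"])
    return table


_SYNONYMS = _load_synonyms()


@dataclass
class GeneFeature:
    """A single annotated gene on the circular genome.

    ``start``/``end`` are 1-based inclusive; ``end < start`` wraps the
    origin. ``strand`` is "J" (majority, GenBank +) or "N" (minority, −).
    """

    name: str
    kind: Kind
    start: int
    end: int
    strand: Literal["J", "N"]
    anticodon_or_product: str | None = None

    def length(self, genome_length: int) -> int:
        if self.end >= self.start:
            return self.end - self.start + 1
        return genome_length - self.start + 1 + self.end

    def wraps(self) -> bool:
        return self.end < self.start


@dataclass
class AnnotatedMitogenome:
    taxon: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    accession: str | None = None
    topology: str = "circular"

    @property
    def length(self) -> int:
        return len(self.sequence)

    def features_of_kind(self, kind: Kind) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == kind]

    def get_feature(self, name: str) -> GeneFeature | None:
        for f in self.features:
            if f.name == name:
                return f
        return None


def normalize_gene_name(raw: str, feature_key: str = "") -> tuple[str, str] | None:
    """Resolve a raw annotation label to (normalized name, kind).

    Returns None when the label is not in the synonym table and cannot be
    parsed as a tRNA product.
    """
    key = raw.strip().upper()
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    # products like "tRNA-Leu (UUR)" / "tRNA-Ser(AGN)"
    if key.startswith("TRNA-"):
        compact = key.replace(" ", "")
        if compact in _SYNONYMS:
            return _SYNONYMS[compact]
        aa = raw.strip()[5:8].capitalize()
        if aa in _AA_TO_TRN:
            return _AA_TO_TRN[aa], "tRNA"
    return None


def circular_slice(sequence: str, start: int, end: int) -> str:
    """1-based inclusive slice on a circular sequence; end < start wraps."""
    n = len(sequence)
    if not (1 <= start <= n and 1 <= end <= n):
        raise ValueError(f"coordinates ({start}, {end}) outside genome of length {n}")
    if end >= start:
        return sequence[start - 1:end]
    return sequence[start - 1:] + sequence[:end]


def extract_gene_sequence(genome: AnnotatedMitogenome, feature: GeneFeature) -> str:
    """Reading-direction sequence of a feature (reverse complement for N)."""
    s = circular_slice(genome.sequence, feature.start, feature.end)
    return revcomp(s) if feature.strand == "N" else s


def rotate_genome(genome: AnnotatedMitogenome, offset: int) -> AnnotatedMitogenome:
    """Move the origin of the circle ``offset`` bases downstream.

    Feature coordinates are remapped; features may begin to wrap. Used for
    rotation-invariance checks of downstream analyses.
    """
    n = genome.length
    offset %= n
    seq = genome.sequence[offset:] + genome.sequence[:offset]

    def shift(pos: int) -> int:
        return (pos - offset - 1) % n + 1

    feats = [replace(f, start=shift(f.start), end=shift(f.end))
             for f in genome.features]
    return replace(genome, sequence=seq, features=feats)


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

def read_genbank(path: str | Path) -> AnnotatedMitogenome:
    """Parse a GenBank flat file into an AnnotatedMitogenome.

    Origin-spanning join() locations are mapped to ``end < start``; strand −
    maps to N, + to J. Unmappable gene labels are kept verbatim with kind
    inferred from the feature key (with a warning).
    """
    record = SeqIO.read(str(path), "genbank")
    if len(record.seq) == 0:
        raise ValueError(f"{path}: GenBank record has no ORIGIN sequence")
    n = len(record.seq)
    features: list[GeneFeature] = []
    for feat in record.features:
        if feat.type not in _KEY_TO_KIND:
            continue
        raw = (feat.qualifiers.get("gene") or feat.qualifiers.get("product")
               or feat.qualifiers.get("note") or ["?"])[0]
        resolved = normalize_gene_name(raw, feat.type)
        if resolved is None:
            warnings.warn(f"unmappable gene name {raw!r}; keeping verbatim")
            name, kind = raw, _KEY_TO_KIND[feat.type]
        else:
            name, kind = resolved
        loc = feat.location
        parts = loc.parts
        if len(parts) == 2 and int(parts[0].end) == n and int(parts[1].start) == 0:
            start, end = int(parts[0].start) + 1, int(parts[1].end)
        else:
            start, end = int(loc.start) + 1, int(loc.end)
        strand = "N" if loc.strand == -1 else "J"
        product = feat.qualifiers.get("product", [None])[0]
        features.append(GeneFeature(name, kind, start, end, strand, product))
    taxon = record.annotations.get("organism") or record.description or record.id
    accession = record.id if record.id and record.id != "<unknown id>" else None
    return AnnotatedMitogenome(
        taxon=taxon.strip(), sequence=str(record.seq).upper(),
        features=features, accession=accession,
        topology=record.annotations.get("topology", "circular"))


def write_genbank(genome: AnnotatedMitogenome, path: str | Path) -> None:
    n = genome.length
    record = SeqRecord(Seq(genome.sequence), id=genome.accession or "synthetic",
                       name=(genome.accession or "SYNTHETIC")[:16],
                       description=genome.taxon)
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = genome.topology
    record.annotations["organism"] = genome.taxon
    for f in genome.features:
        strand = -1 if f.strand == "N" else 1
        if f.wraps():
            loc = CompoundLocation([
                SimpleLocation(f.start - 1, n, strand),
                SimpleLocation(0, f.end, strand),
            ])
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand)
        qualifiers = {"gene": [f.name]}
        if f.kind == "PCG":
            qualifiers["transl_table"] = ["5"]
        if f.anticodon_or_product:
            qualifiers["product"] = [f.anticodon_or_product]
        record.features.append(SeqFeature(loc, type=_FEATURE_KEY[f.kind],
                                          qualifiers=qualifiers))
    SeqIO.write([record], str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA + feature table TSV
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["taxon", "name", "kind", "start", "end", "strand"]


def write_fasta(genome: AnnotatedMitogenome, path: str | Path) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.accession or genome.taxon.replace(" ", "_"),
                    description=genome.taxon)
    SeqIO.write([rec], str(path), "fasta")


def write_feature_table(genome: AnnotatedMitogenome, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for f in genome.features:
            writer.writerow([genome.taxon, f.name, f.kind, f.start, f.end, f.strand])


def read_feature_table(fasta_path: str | Path, tsv_path: str | Path) -> AnnotatedMitogenome:
    record = SeqIO.read(str(fasta_path), "fasta")
    features: list[GeneFeature] = []
    taxon = record.description.split(None, 1)[-1] if " " in record.description else record.id
    seen: set[tuple[str, int]] = set()
    with open(tsv_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            taxon = row["taxon"] or taxon
            key = (row["name"], int(row["start"]))
            if key in seen:
                raise ValueError(f"duplicate feature {key} in {tsv_path}")
            seen.add(key)
            features.append(GeneFeature(row["name"], row["kind"],
                                        int(row["start"]), int(row["end"]),
                                        row["strand"]))
    return AnnotatedMitogenome(taxon=taxon, sequence=str(record.seq).upper(),
                               features=features)


def read_genomes_dir(directory: str | Path, pattern: str = "*.gb") -> list[AnnotatedMitogenome]:
    """Read every GenBank file matching ``pattern`` in a directory, sorted by name."""
    paths = sorted(Path(directory).glob(pattern))
    return [read_genbank(p) for p in paths]


def sorted_features(genome: AnnotatedMitogenome) -> list[GeneFeature]:
    """Features in genomic order: by start, longer first on ties."""
    n = genome.length
    return sorted(genome.features, key=lambda f: (f.start, -f.length(n)))
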