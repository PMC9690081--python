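"""Annotated mitochondrial genomes: GenBank/FASTA I/O, CDS extraction,
gene orders and translation.

Coordinates are 0-based half-open internally; the GenBank boundary uses
the format's 1-based inclusive convention (handled by Biopython).
Features spanning the origin of a circular genome are linearized by
rotating the sequence at read time; the applied offset is recorded on the
genome so positions can be mapped back.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .codes import GeneticCode, genetic_code

log = logging.getLogger(__name__)

PCG, TRNA, RRNA, CONTROL, OTHER = "PCG", "tRNA", "rRNA", "control_region", "other"
FEATURE_CLASSES = (PCG, TRNA, RRNA, CONTROL, OTHER)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Canonical protein-coding gene labels of a bilaterian mitogenome.
CANONICAL_PCGS = (
    "COX1", "COX2", "COX3", "CYTB", "ATP6", "ATP8",
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
)

# Mixed spellings seen in deposited records and figure legends.
_LABEL_ALIASES = {
    "COI": "COX1", "COII": "COX2", "COIII": "COX3",
    "CO1": "COX1", "CO2": "COX2", "CO3": "COX3",
    "COXI": "COX1", "COXII": "COX2", "COXIII": "COX3",
    "CYB": "CYTB", "COB": "CYTB", "CYTOCHROME B": "CYTB",
    "NAD1": "ND1", "NAD2": "ND2", "NAD3": "ND3", "NAD4": "ND4",
    "NAD4L": "ND4L", "NAD5": "ND5", "NAD6": "ND6",
    "ATPASE6": "ATP6", "ATPASE8": "ATP8", "ATP 6": "ATP6", "ATP 8": "ATP8",
    "L-RRNA": "rrnL", "S-RRNA": "rrnS", "16S": "rrnL", "12S": "rrnS",
    "RRNL": "rrnL", "RRNS": "rrnS", "16S RIBOSOMAL RNA": "rrnL",
    "12S RIBOSOMAL RNA": "rrnS",
    "D-LOOP": "D-loop", "CONTROL REGION": "D-loop", "CR": "D-loop",
}

_AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def normalize_label(raw: str, anticodon: str | None = None) -> str:
    """Map a record's gene label onto the canonical naming scheme.

    PCGs become COX1..COX3/ND1..ND6/ND4L/ATP6/ATP8/CYTB, ribosomal RNAs
    rrnL/rrnS, the control region D-loop, and tRNAs trnX-ANTICODON.
    Unknown labels pass through unchanged.
    """
    s = raw.strip()
    key = s.upper().replace("_", " ")
    if key in _LABEL_ALIASES:
        return _LABEL_ALIASES[key]
    if key in CANONICAL_PCGS:
        return key
    m = re.match(r"^TRN([A-Z])[- ]?\(?([ACGTU]{3})?\)?$", key)
    if m:
        aa, ac = m.group(1), m.group(2)
        return f"trn{aa}-{ac.replace('U', 'T')}" if ac else f"trn{aa}"
    m = re.match(r"^TRNA[- ]([A-Z]{3})\)?(?:[- ;(]*([ACGTU]{3}))?\)?$", key)
    if m and m.group(1) in _AA3_TO_1:
        aa = _AA3_TO_1[m.group(1)]
        ac = m.group(2)
        return f"trn{aa}-{ac.replace('U', 'T')}" if ac else f"trn{aa}"
    if re.match(r"^trn[A-Z](-[ACGT]{3})?$", s):
        return s
    return s


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def translate(seq: str, code: GeneticCode | int = 5) -> str:
    """Codon-wise translation; codons containing N translate to 'X',
    stops to '*'.  Trailing 1-2 bases are ignored."""
    if isinstance(code, int):
        code = genetic_code(code)
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    seq = seq.upper()
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i:i + 3]
        out.append("X" if "N" in codon else code.aa(codon))
    return "".join(out)


@dataclass(frozen=True)
class GeneFeature:
    """One typed feature on a genome (0-based half-open coordinates)."""

    name: str
    feature_class: str
    start: int
    end: int
    strand: str = "+"
    copy_index: int = 1

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.copy_index < 1:
            raise ValueError("copy_index starts at 1")
        if self.feature_class == PCG and self.end - self.start < 3:
            raise ValueError("PCG shorter than one codon")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AnnotatedGenome:
    """A (typically circular) annotated mitochondrial genome."""

    id: str
    sequence: str
    circular: bool = True
    features: tuple[GeneFeature, ...] = ()
    source_format: str = "synthetic"
    rotation_offset: int = 0   # bases the original sequence was rotated by

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        seq = self.sequence.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(
                f"sequence contains unsupported letters {sorted(bad)}; "
                "only A/C/G/T and the ambiguity code N are accepted"
            )
        object.__setattr__(self, "sequence", seq)
        feats = tuple(sorted(self.features, key=lambda f: (f.start, f.end)))
        for f in feats:
            if f.end > len(seq):
                raise ValueError(f"feature {f.name} exceeds genome length")
        seen = set()
        for f in feats:
            key = (f.name, f.copy_index)
            if key in seen:
                raise ValueError(f"duplicate feature identity {key}")
            seen.add(key)
        object.__setattr__(self, "features", feats)

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, feature: GeneFeature, oriented: bool = True) -> str:
        s = self.sequence[feature.start:feature.end]
        if oriented and feature.strand == "-":
            s = reverse_complement(s)
        return s

    def features_of_class(self, *classes: str) -> tuple[GeneFeature, ...]:
        want = set(classes)
        return tuple(f for f in self.features if f.feature_class in want)


@dataclass(frozen=True)
class CdsRecord:
    """An extracted coding sequence in reading orientation."""

    name: str
    copy_index: int
    sequence: str
    protein: str
    strand: str = "+"
    flags: tuple[str, ...] = ()


def assign_copy_indices(features: list[GeneFeature]) -> list[GeneFeature]:
    """Number duplicate gene names 1, 2, ... in coordinate order."""
    counts: dict[str, int] = {}
    out = []
    for f in sorted(features, key=lambda f: (f.start, f.end)):
        counts[f.name] = counts.get(f.name, 0) + 1
        out.append(replace(f, copy_index=counts[f.name]))
    return out


def _classify(ftype: str, qualifiers: dict) -> str | None:
    if ftype == "CDS":
        return PCG
    if ftype == "tRNA":
        return TRNA
    if ftype == "rRNA":
        return RRNA
    if ftype in ("D-loop", "rep_origin"):
        return CONTROL
    if ftype == "misc_feature":
        note = " ".join(qualifiers.get("note", [])).lower()
        if "control region" in note or "d-loop" in note:
            return CONTROL
    if ftype in ("gene", "source"):
        return None          # container/bookkeeping features
    return None


def _feature_label(feat: SeqFeature) -> str:
    q = feat.qualifiers
    for key in ("gene", "product", "note"):
        if key in q and q[key]:
            return str(q[key][0])
    return feat.type


def read_genbank(path) -> AnnotatedGenome:
    """Read one GenBank flat file into an :class:`AnnotatedGenome`.

    CDS/tRNA/rRNA/D-loop features are mapped to feature classes, labels
    are normalized, duplicates get copy_index 2, 3, ... in coordinate
    order.  A feature spanning the origin of a circular record triggers a
    rotation of the whole sequence so that every interval is contiguous.
    """
    record = SeqIO.read(path, "genbank")
    seq = str(record.seq).upper()
    if not seq or set(seq) == {"N"} or len(seq) == 0:
        raise ValueError(f"{path}: GenBank record has no usable sequence")
    circular = record.annotations.get("topology", "linear") == "circular"

    rotation = 0
    wrapping = [
        f for f in record.features
        if len(f.location.parts) > 1
        and int(f.location.parts[0].end) == len(seq)
        and int(f.location.parts[-1].start) == 0
    ]
    if wrapping and circular:
        rotation = int(wrapping[0].location.parts[0].start)
        seq = seq[rotation:] + seq[:rotation]

    feats: list[GeneFeature] = []
    for f in record.features:
        fclass = _classify(f.type, f.qualifiers)
        if fclass is None:
            continue
        raw = _feature_label(f)
        anticodon = None
        if "anticodon" in f.qualifiers:
            m = re.search(r"seq:([acgtu]{3})", f.qualifiers["anticodon"][0])
            if m:
                anticodon = m.group(1).upper()
        name = normalize_label(raw, anticodon)
        if fclass == OTHER or (
            fclass == PCG and name not in CANONICAL_PCGS
        ):
            log.warning("unknown gene label %r kept with class 'other'", raw)
            fclass = OTHER
        start = (int(f.location.start) - rotation) % len(seq)
        end_raw = (int(f.location.end) - rotation) % len(seq)
        end = end_raw if end_raw > start else len(seq) if end_raw == 0 else end_raw
        if end <= start:
            raise ValueError(
                f"{path}: feature {name} has non-contiguous coordinates "
                "after linearization"
            )
        if end > len(seq):
            raise ValueError(f"{path}: feature {name} outside sequence")
        strand = "-" if f.location.strand == -1 else "+"
        feats.append(GeneFeature(name, fclass, start, end, strand))

    return AnnotatedGenome(
        id=record.id or record.name,
        sequence=seq,
        circular=circular,
        features=tuple(assign_copy_indices(feats)),
        source_format="genbank",
        rotation_offset=rotation,
    )


def write_genbank(genome: AnnotatedGenome, path) -> None:
    """Write an :class:`AnnotatedGenome` back out as a GenBank flat file."""
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                    description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if genome.circular else "linear"
    type_of = {PCG: "CDS", TRNA: "tRNA", RRNA: "rRNA", CONTROL: "D-loop",
               OTHER: "misc_feature"}
    for f in genome.features:
        loc = FeatureLocation(f.start, f.end, strand=-1 if f.strand == "-" else 1)
        rec.features.append(
            SeqFeature(loc, type=type_of[f.feature_class],
                       qualifiers={"gene": [f.name]})
        )
    SeqIO.write([rec], path, "genbank")


def read_fasta(path) -> list[tuple[str, str]]:
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(path, "fasta")]
    if not records:
        raise ValueError(f"{path}: empty FASTA file")
    return records


def write_fasta(records, path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records],
        path, "fasta",
    )


def extract_cds(genome: AnnotatedGenome, code: GeneticCode | int = 5) -> list[CdsRecord]:
    """Extract every protein-coding feature in reading orientation.

    Minus-strand features are reverse-complemented; the protein drops the
    trailing stop.  Internal stops and lengths not divisible by 3 are
    flagged on the record (and logged), never fatal.
    """
    if isinstance(code, int):
        code = genetic_code(code)
    pcgs = genome.features_of_class(PCG)
    if not pcgs:
        raise ValueError(f"{genome.id}: no protein-coding features")
    out = []
    for f in pcgs:
        seq = genome.slice(f, oriented=True)
        flags: list[str] = []
        if len(seq) % 3:
            flags.append("length_not_multiple_of_3")
            log.warning("%s %s: length %d not divisible by 3; trailing "
                        "bases dropped for translation", genome.id, f.name, len(seq))
        prot = translate(seq, code)
        if prot.endswith("*"):
            prot = prot[:-1]
        if "*" in prot:
            flags.append("internal_stop")
            log.warning("%s %s: internal stop codon", genome.id, f.name)
        out.append(CdsRecord(f.name, f.copy_index, seq, prot, f.strand,
                             tuple(flags)))
    return out


def gene_order_of(genome: AnnotatedGenome, classes=None):
    """The genome's gene order: (label, strand) by start coordinate.

    The linearization origin is the genome's own coordinate origin (after
    any read-time rotation, which is recorded on the genome).
    """
    from .gene_order import GeneOrder

    feats = genome.features if classes is None else genome.features_of_class(*classes)
    return GeneOrder(
        id=genome.id,
        items=tuple((f.name, f.strand) for f in feats),
        circular=genome.circular,
    )


def feature_table(genome: AnnotatedGenome):
    """Per-feature table (name, class, start, end, strand, length)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {"name": f.name, "copy": f.copy_index, "class": f.feature_class,
             "start": f.start, "end": f.end, "strand": f.strand,
             "length": f.length}
            for f in genome.features
        ]
    )
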