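"""Model of a two-region segmental-duplication locus.

The immunoglobulin kappa (IGK) locus consists of two large, highly
similar regions ("proximal" and "distal") that arose by segmental
duplication.  Genes in the distal region carry a ``D`` infix in their
names (``IGKV1-13`` / ``IGKV1D-13``).  This module represents the locus
geometry — region bounds, per-gene features (leader, intron, coding
exon, recombination signal sequence), paralog pairing between the two
regions, structural-variant definitions, and the gene-conversion
acceptor window — loaded from a BED-like annotation table so that
reduced synthetic loci can be modelled with the same machinery.

Coordinates are 0-based half-open throughout; conversion to 1-based
happens only at VCF emission.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ValidationError

V_FEATURES = ("L-Part1", "intron", "V-exon", "RSS")
EXON_FEATURES = ("V-exon", "J-exon", "C-exon")
FEATURE_TAGS = ("L-Part1", "intron", "V-exon", "J-exon", "C-exon", "RSS")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.contig}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}"


@dataclass
class GeneAnnotation:
    """One gene with its per-feature intervals.

    V genes carry L-Part1, intron, V-exon and RSS features; J genes a
    J-exon and RSS; the single C gene a C-exon.
    """

    gene_name: str
    region_tag: str  # "proximal" | "distal"
    gene_type: str  # "V" | "J" | "C"
    functional_class: str  # "functional" | "ORF" | "pseudogene"
    strand: str  # "+" | "-"
    features: dict[str, GenomicInterval] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.region_tag not in ("proximal", "distal"):
            raise ValidationError(f"{self.gene_name}: bad region_tag {self.region_tag}")
        if self.gene_type not in ("V", "J", "C"):
            raise ValidationError(f"{self.gene_name}: bad gene_type {self.gene_type}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_name}: bad strand {self.strand}")

    @property
    def exon(self) -> GenomicInterval:
        """The coding-exon feature (V-exon, J-exon or C-exon)."""
        for tag in EXON_FEATURES:
            if tag in self.features:
                return self.features[tag]
        raise ValidationError(f"{self.gene_name}: no exon feature annotated")

    def footprint(self) -> GenomicInterval:
        """Smallest interval covering every annotated feature."""
        ivals = list(self.features.values())
        return GenomicInterval(
            ivals[0].contig,
            min(iv.start for iv in ivals),
            max(iv.end for iv in ivals),
        )

    def validate(self) -> None:
        required = {
            "V": set(V_FEATURES),
            "J": {"J-exon", "RSS"},
            "C": {"C-exon"},
        }[self.gene_type]
        missing = required - set(self.features)
        if missing:
            raise ValidationError(
                f"{self.gene_name}: missing features {sorted(missing)}"
            )
        ivals = sorted(self.features.values())
        for a, b in zip(ivals, ivals[1:]):
            if a.overlaps(b):
                raise ValidationError(
                    f"{self.gene_name}: overlapping features {a} and {b}"
                )


@dataclass
class SvDefinition:
    """A structural variant relative to the SV-inclusive reference.

    For an insertion the anchor is the payload's footprint in the
    reference that carries it (so the 'deleted' state is a haplotype
    lacking the anchor).  For an inversion the anchor is the inverted
    span; payload_length equals the anchor length.
    """

    sv_id: str
    kind: str  # "insertion" | "inversion"
    anchor: GenomicInterval
    payload_length: int
    carried_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "inversion"):
            raise ValidationError(f"{self.sv_id}: bad kind {self.kind}")
        if self.kind == "insertion" and self.payload_length <= 0:
            raise ValidationError(f"{self.sv_id}: insertion payload must be > 0")
        if self.kind == "inversion" and self.payload_length != self.anchor.length():
            raise ValidationError(
                f"{self.sv_id}: inversion payload_length must equal anchor length"
            )


_D_INFIX = re.compile(r"^(IGK[A-Z]\d+)(D?)-(.+)$")


def _toggle_d_infix(name: str) -> str | None:
    """IGKV1-13 <-> IGKV1D-13 by inserting/removing the distal infix."""
    m = _D_INFIX.match(name)
    if not m:
        return None
    head, d, tail = m.groups()
    return f"{head}-{tail}" if d else f"{head}D-{tail}"


@dataclass
class LocusMap:
    proximal: GenomicInterval
    distal: GenomicInterval
    genes: list[GeneAnnotation]
    paralog_pairs: list[tuple[str, str]] = field(default_factory=list)
    sv_definitions: list[SvDefinition] = field(default_factory=list)
    conversion_window: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.proximal.overlaps(self.distal):
            raise ValidationError("proximal and distal regions overlap")
        self.genes = sorted(self.genes, key=lambda g: g.footprint().start)
        self._by_name = {g.gene_name: g for g in self.genes}
        if len(self._by_name) != len(self.genes):
            raise ValidationError("duplicate gene names in locus")
        if self.conversion_window is not None and not self.distal.contains_interval(
            self.conversion_window
        ):
            raise ValidationError("conversion_window must lie within the distal region")
        if not self.paralog_pairs:
            self.paralog_pairs = self._infer_pairs()
        for p, d in self.paralog_pairs:
            if self._by_name[p].region_tag != "proximal":
                raise ValidationError(f"paralog pair ({p},{d}): {p} is not proximal")
            if self._by_name[d].region_tag != "distal":
                raise ValidationError(f"paralog pair ({p},{d}): {d} is not distal")

    def _infer_pairs(self) -> list[tuple[str, str]]:
        pairs = []
        for g in self.genes:
            if g.region_tag != "proximal":
                continue
            mate = _toggle_d_infix(g.gene_name)
            if mate is not None and mate in self._by_name:
                pairs.append((g.gene_name, mate))
        return pairs

    def gene(self, name: str) -> GeneAnnotation:
        try:
            return self._by_name[name]
        except KeyError:
            raise ValidationError(f"unknown gene {name!r}") from None

    def gene_names(self) -> list[str]:
        return [g.gene_name for g in self.genes]

    def region(self, tag: str) -> GenomicInterval:
        if tag == "proximal":
            return self.proximal
        if tag == "distal":
            return self.distal
        raise ValidationError(f"unknown region tag {tag!r}")

    def paralog_of(self, gene_name: str) -> str | None:
        """Paralogous mate of a gene, or None for unpaired genes.

        Pairing is symmetric: paralog_of(paralog_of(g)) == g.
        """
        self.gene(gene_name)  # raises on unknown gene
        for p, d in self.paralog_pairs:
            if gene_name == p:
                return d
            if gene_name == d:
                return p
        return None

    def sv(self, sv_id: str) -> SvDefinition:
        for sv in self.sv_definitions:
            if sv.sv_id == sv_id:
                return sv
        raise ValidationError(f"unknown SV {sv_id!r}")

    def validate(self) -> None:
        for g in self.genes:
            g.validate()
            region = self.region(g.region_tag)
            for tag, iv in g.features.items():
                if not region.contains_interval(iv):
                    raise ValidationError(
                        f"{g.gene_name}/{tag}: {iv} outside {g.region_tag} region"
                    )
            # the distal-name convention: a "D" locality infix marks distal
            # genes; the not-localized insertion gene is exempt
            mate = _toggle_d_infix(g.gene_name)
            if mate is not None and "NL" not in g.gene_name:
                has_d = _D_INFIX.match(g.gene_name).group(2) == "D"
                if has_d != (g.region_tag == "distal"):
                    raise ValidationError(
                        f"{g.gene_name}: name/region_tag mismatch"
                    )


def paralog_of(gene_name: str, locus: LocusMap) -> str | None:
    """Functional wrapper around :meth:`LocusMap.paralog_of`."""
    return locus.paralog_of(gene_name)


# ---------------------------------------------------------------------------
# Annotation table IO.  One row per feature, tab-separated:
#   contig  start  end  name  feature  strand  region  class  [attrs]
# Feature rows carry gene features; 'region' rows declare the two region
# bounds; 'conversion_window' declares the acceptor window; 'sv' rows
# declare structural variants with key=value attrs.
# ---------------------------------------------------------------------------

_COLUMNS = ("contig", "start", "end", "name", "feature", "strand", "region", "class")


def load_locus(path) -> LocusMap:
    """Load a LocusMap from the BED-like annotation TSV."""
    regions: dict[str, GenomicInterval] = {}
    genes: dict[str, GeneAnnotation] = {}
    svs: list[SvDefinition] = []
    conv: GenomicInterval | None = None
    pairs: list[tuple[str, str]] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValidationError(
                    f"{path}: row {lineno}: expected >=8 columns, got {len(fields)}"
                )
            contig, start, end, name, feat, strand, region, fclass = fields[:8]
            attrs = _parse_attrs(fields[8]) if len(fields) > 8 else {}
            try:
                iv = GenomicInterval(contig, int(start), int(end))
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path}: row {lineno}: {exc}") from None
            if feat == "region":
                regions[region] = iv
            elif feat == "conversion_window":
                conv = iv
            elif feat == "sv":
                svs.append(
                    SvDefinition(
                        sv_id=name,
                        kind=attrs.get("kind", "insertion"),
                        anchor=iv,
                        payload_length=int(attrs.get("payload_length", iv.length())),
                        carried_genes=[
                            g for g in attrs.get("carried_genes", "").split(",") if g
                        ],
                    )
                )
            elif feat in FEATURE_TAGS:
                gene_type = attrs.get("gene_type") or _gene_type_from_feature(feat)
                g = genes.get(name)
                if g is None:
                    g = GeneAnnotation(
                        gene_name=name,
                        region_tag=region,
                        gene_type=gene_type,
                        functional_class=fclass,
                        strand=strand,
                    )
                    genes[name] = g
                    if "paralog" in attrs:
                        mate = attrs["paralog"]
                        pair = (name, mate) if region == "proximal" else (mate, name)
                        if pair not in pairs:
                            pairs.append(pair)
                if feat in g.features:
                    raise ValidationError(
                        f"{path}: row {lineno}: duplicate feature {feat} for {name}"
                    )
                g.features[feat] = iv
            else:
                raise ValidationError(
                    f"{path}: row {lineno}: unknown feature tag {feat!r}"
                )

    if "proximal" not in regions or "distal" not in regions:
        raise ValidationError(f"{path}: missing proximal/distal region rows")
    locus = LocusMap(
        proximal=regions["proximal"],
        distal=regions["distal"],
        genes=sorted(genes.values(), key=lambda g: g.footprint().start),
        paralog_pairs=pairs,
        sv_definitions=svs,
        conversion_window=conv,
    )
    locus.validate()
    return locus


def write_locus(locus: LocusMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_COLUMNS + ("attrs",)) + "\n")
        for tag in ("proximal", "distal"):
            iv = locus.region(tag)
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{tag}\tregion\t+\t{tag}\t.\t.\n"
            )
        if locus.conversion_window is not None:
            iv = locus.conversion_window
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\tconversion\tconversion_window"
                f"\t+\tdistal\t.\t.\n"
            )
        for sv in locus.sv_definitions:
            iv = sv.anchor
            attrs = (
                f"kind={sv.kind};payload_length={sv.payload_length};"
                f"carried_genes={','.join(sv.carried_genes)}"
            )
            region = "distal" if locus.distal.overlaps(iv) else "proximal"
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{sv.sv_id}\tsv\t+\t{region}"
                f"\t.\t{attrs}\n"
            )
        explicit = {name for pair in locus.paralog_pairs for name in pair}
        for g in locus.genes:
            for tag in FEATURE_TAGS:
                if tag not in g.features:
                    continue
                iv = g.features[tag]
                attrs = [f"gene_type={g.gene_type}"]
                if g.gene_name in explicit and tag == sorted(g.features)[0]:
                    mate = locus.paralog_of(g.gene_name)
                    if mate is not None:
                        attrs.append(f"paralog={mate}")
                fh.write(
                    f"{iv.contig}\t{iv.start}\t{iv.end}\t{g.gene_name}\t{tag}\t"
                    f"{g.strand}\t{g.region_tag}\t{g.functional_class}\t"
                    f"{';'.join(attrs)}\n"
                )


def _parse_attrs(text: str) -> dict[str, str]:
    if text in (".", ""):
        return {}
    out = {}
    for item in text.split(";"):
        if not item:
            continue
        if "=" not in item:
            raise ValidationError(f"malformed attrs item {item!r}")
        k, v = item.split("=", 1)
        out[k] = v
    return out


def _gene_type_from_feature(feat: str) -> str:
    return {"J-exon": "J", "C-exon": "C"}.get(feat, "V")
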