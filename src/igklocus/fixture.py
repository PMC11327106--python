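"""Synthetic locus fixtures emulating the IGK architecture.

The default desk-scale fixture has two 50 Kbp paralogous regions on one
contig, separated by a 2 Kbp N-masked gap, with a 2 Kbp insertion-SV
payload carrying one extra V gene spliced into the distal region.  The
distal region is a copy of the proximal region diverged at ~1% of
positions, so paralog identity and gene-conversion signatures behave as
in a real segmental duplication, at a size where full-cohort analyses
run in seconds.  A miniature variant (two 8 Kbp regions) serves
replicate-heavy statistical tests.

Default layout (custom coordinates, contig ``igk_synth``):

* proximal region  [0, 50000)        IGKV1-12 IGKV1-13 IGKV3-20 IGKV1-27 IGKJ1 IGKC
* N-masked gap     [50000, 52000)
* distal region    [52000, 104000)   IGKV1D-12 IGKV1D-13 IGKV3D-20 IGKV2D-40(-)
                                     SV payload [92000, 94000) carrying IGKV1-NL1
                                     IGKV1D-27
* conversion acceptor window [62000, 65000) covering IGKV1D-12/13
* inversion anchor between the IGKV1-27 / IGKV1D-27 footprint midpoints

References are generated deterministically (fixed internal seeds) via
the reference-editing machinery; the default annotation ships as
packaged data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .locus import GeneAnnotation, GenomicInterval, LocusMap, SvDefinition
from .reference import EditLedger, ReferenceEdit, build_custom_reference

CONTIG = "igk_synth"
PARALOG_DIVERGENCE = 0.01
_FIXTURE_SEED = 20_402_117  # fixed: each fixture is one object, not a dial

# V genes share one feature shape (offsets relative to the gene start)
_V_SHAPE = {
    "L-Part1": (0, 60),
    "intron": (60, 360),
    "V-exon": (360, 660),
    "RSS": (660, 688),
}
V_FOOTPRINT = 688


@dataclass
class LocusLayout:
    """Geometry of one synthetic locus fixture."""

    region_len: int
    gap_len: int
    payload_len: int
    payload_offset: int  # insertion point, distal-region offset
    v_offsets: dict[str, int]  # proximal V genes; distal copies derived
    window_offsets: tuple[int, int]  # conversion acceptor, region offsets
    nl1_offset: int  # carried gene start within the payload
    include_jc: bool = True
    jc_offsets: tuple[int, int] = (47_000, 48_000)
    minus_strand_gene: tuple[str, int] | None = ("IGKV2D-40", 30_000)
    inversion_anchor_gene: str = "IGKV1-27"
    seed: int = _FIXTURE_SEED

    @property
    def distal_start(self) -> int:
        return self.region_len + self.gap_len


DEFAULT_LAYOUT = LocusLayout(
    region_len=50_000,
    gap_len=2_000,
    payload_len=2_000,
    payload_offset=40_000,
    v_offsets={
        "IGKV1-12": 10_200,
        "IGKV1-13": 11_800,
        "IGKV3-20": 25_000,
        "IGKV1-27": 45_000,
    },
    window_offsets=(10_000, 13_000),
    nl1_offset=600,
)

TINY_LAYOUT = LocusLayout(
    region_len=8_000,
    gap_len=500,
    payload_len=1_000,
    payload_offset=5_000,
    v_offsets={"IGKV1-12": 900, "IGKV1-13": 2_300, "IGKV1-27": 6_500},
    window_offsets=(800, 3_100),
    nl1_offset=150,
    include_jc=False,
    minus_strand_gene=None,
    seed=_FIXTURE_SEED + 1,
)


def _v_gene(name, region_tag, start, strand="+", fclass="functional"):
    return GeneAnnotation(
        gene_name=name,
        region_tag=region_tag,
        gene_type="V",
        functional_class=fclass,
        strand=strand,
        features={
            tag: GenomicInterval(CONTIG, start + a, start + b)
            for tag, (a, b) in _V_SHAPE.items()
        },
    )


def build_locus_map(layout: LocusLayout = DEFAULT_LAYOUT) -> LocusMap:
    genes = []
    for name, off in layout.v_offsets.items():
        genes.append(_v_gene(name, "proximal", off))
    if layout.include_jc:
        j0, c0 = layout.jc_offsets
        genes.append(
            GeneAnnotation(
                "IGKJ1", "proximal", "J", "functional", "+",
                {
                    "J-exon": GenomicInterval(CONTIG, j0, j0 + 39),
                    "RSS": GenomicInterval(CONTIG, j0 + 50, j0 + 78),
                },
            )
        )
        genes.append(
            GeneAnnotation(
                "IGKC", "proximal", "C", "functional", "+",
                {"C-exon": GenomicInterval(CONTIG, c0, c0 + 321)},
            )
        )
    for name, off in layout.v_offsets.items():
        head, tail = name.split("-")
        dname = f"{head}D-{tail}"
        start = layout.distal_start + off + (
            layout.payload_len if off >= layout.payload_offset else 0
        )
        genes.append(_v_gene(dname, "distal", start))
    if layout.minus_strand_gene is not None:
        mname, moff = layout.minus_strand_gene
        genes.append(_v_gene(mname, "distal", layout.distal_start + moff, strand="-"))
    payload_start = layout.distal_start + layout.payload_offset
    genes.append(_v_gene("IGKV1-NL1", "distal", payload_start + layout.nl1_offset))

    def _midpoint(g):
        fp = g.footprint()
        return (fp.start + fp.end) // 2

    by_name = {g.gene_name: g for g in genes}
    anchor_p = layout.inversion_anchor_gene
    head, tail = anchor_p.split("-")
    anchor_d = f"{head}D-{tail}"
    inv_left = _midpoint(by_name[anchor_p])
    inv_right = _midpoint(by_name[anchor_d])
    svs = [
        SvDefinition(
            sv_id="IGKV1-NL1_ins",
            kind="insertion",
            anchor=GenomicInterval(
                CONTIG, payload_start, payload_start + layout.payload_len
            ),
            payload_length=layout.payload_len,
            carried_genes=["IGKV1-NL1"],
        ),
        SvDefinition(
            sv_id="INV_27",
            kind="inversion",
            anchor=GenomicInterval(CONTIG, inv_left, inv_right),
            payload_length=inv_right - inv_left,
            carried_genes=[],
        ),
    ]
    locus = LocusMap(
        proximal=GenomicInterval(CONTIG, 0, layout.region_len),
        distal=GenomicInterval(
            CONTIG,
            layout.distal_start,
            layout.distal_start + layout.region_len + layout.payload_len,
        ),
        genes=genes,
        sv_definitions=svs,
        conversion_window=GenomicInterval(
            CONTIG,
            layout.distal_start + layout.window_offsets[0],
            layout.distal_start + layout.window_offsets[1],
        ),
    )
    locus.validate()
    return locus


def build_reference(layout: LocusLayout = DEFAULT_LAYOUT) -> tuple[str, EditLedger]:
    """Deterministic fixture reference via the editing machinery."""
    rng = np.random.default_rng(layout.seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    proximal = rng.choice(bases, layout.region_len)
    gap = rng.choice(bases, layout.gap_len)
    distal = proximal.copy()
    div = np.nonzero(rng.random(layout.region_len) < PARALOG_DIVERGENCE)[0]
    for p in div:
        choices = bases[bases != distal[p]]
        distal[p] = rng.choice(choices)
    # every paired exon must carry divergence so paralog alleles differ
    a, b = _V_SHAPE["V-exon"]
    for name, off in layout.v_offsets.items():
        lo, hi = off + a, off + b
        if not ((div >= lo) & (div < hi)).any():
            p = lo + 10
            choices = bases[bases != distal[p]]
            distal[p] = rng.choice(choices)
    payload = rng.choice(bases, layout.payload_len)
    base = (proximal.tobytes() + gap.tobytes() + distal.tobytes()).decode()
    insert_at = layout.distal_start + layout.payload_offset
    edits = [
        ReferenceEdit("n_mask", CONTIG, layout.region_len, layout.distal_start),
        ReferenceEdit(
            "insert", CONTIG, insert_at, insert_at, payload.tobytes().decode()
        ),
    ]
    return build_custom_reference(base, edits)


def default_locus_map() -> LocusMap:
    return build_locus_map(DEFAULT_LAYOUT)


def build_default_reference(locus=None) -> tuple[str, EditLedger]:
    return build_reference(DEFAULT_LAYOUT)


def default_locus(from_packaged_annotation: bool = False):
    """The packaged desk-scale locus: (LocusMap, reference sequence).

    With ``from_packaged_annotation`` the map is read back from the
    shipped annotation TSV instead of being constructed in code.
    """
    if from_packaged_annotation:
        from .locus import load_locus

        with resources.as_file(
            resources.files("igklocus") / "data" / "igk_synthetic_locus.tsv"
        ) as path:
            locus = load_locus(path)
    else:
        locus = build_locus_map(DEFAULT_LAYOUT)
    reference, _ledger = build_reference(DEFAULT_LAYOUT)
    return locus, reference


def tiny_locus():
    """Miniature locus (two 8 Kbp regions) for replicate-heavy tests."""
    locus = build_locus_map(TINY_LAYOUT)
    reference, _ledger = build_reference(TINY_LAYOUT)
    return locus, reference
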