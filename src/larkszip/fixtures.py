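"""Bundled reference data: the KRT8 head-domain and alpha-synuclein sequences,
the crystallised KRT8 segment pairs, the experimentally characterised
variant list, and metadata for the three deposited fibril structures.

These strings are the package's built-in positive controls: threshold
calibration and the worked examples in the test suite run against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import ProteinRecord, VariantRecord

#: residues 2-90 of human keratin-8 (the head domain without the initiator
#: methionine, hence numbering_offset=2)
KRT8_HEAD_SEQUENCE = (
    "SIRVTQKSYKVSTSGPRAFSSRSYTSGPGSRISSSSFSRVGSSNFRGGLGGGYGGASGM"
    "GGITAVTVNQSLLSPLVLEVDPNIQAVRTQ"
)

#: full-length human alpha-synuclein (140 aa); its NACore region is the
#: hydrophobic stretch QVTNVGGAVVTGVTAV
ALPHA_SYNUCLEIN_SEQUENCE = (
    "MDVFMKGLSKAKEGVVAAAEKTKQGVAEAAGKTKEGVLYVGSKTKEGVVHGVATVAEKTKE"
    "QVTNVGGAVVTGVTAVAQKTVEGAGSIAAATGFVKKDQLGKNEEGAPQEGILEDMPVDPDN"
    "EAYEMPSEEGYQDYEPEA"
)

#: hydrophobic stretch of the KRT8 head resembling the alpha-synuclein NACore
KRT8_HYDROPHOBIC_REGION = "GGITAVTVNQ"
ASYN_NACORE_REGION = "QVTNVGGAVVTGVTAV"


@dataclass(frozen=True)
class SegmentPair:
    """A crystallised wild-type/mutant LARKS segment pair (7-mer naming)."""

    protein_id: str
    start: int
    end: int
    wt_segment: str | None   # None when no wild-type structure exists
    mut_segment: str
    variant: VariantRecord


@dataclass(frozen=True)
class DepositedStructure:
    """Metadata for a deposited KRT8 segment fibril structure."""

    pdb_id: str
    segment: str
    zipper_class: int
    within_sheet: str  # parallel | antiparallel


@dataclass
class FixtureBundle:
    krt8: ProteinRecord
    alpha_synuclein: ProteinRecord
    segment_pairs: list[SegmentPair]
    variants: list[VariantRecord]
    deposited: list[DepositedStructure]
    unparsed_note: str = field(default=(
        "Ambiguous upstream segment entries are excluded; only "
        "unambiguous records are bundled."))


def reference_fixtures() -> FixtureBundle:
    """The bundled control data set.

    Returns the two reference sequences (with numbering offsets), the
    crystallised KRT8 segment pairs (SGMGGIT/SGMGCIT for G62C and
    GGYGGAS/GGYAGAS for G55A; Y54H has no crystallised wild-type/mutant
    pair), the six experimentally characterised variants, and the deposited
    structure metadata.
    """
    krt8 = ProteinRecord("KRT8", KRT8_HEAD_SEQUENCE, numbering_offset=2)
    asyn = ProteinRecord("SNCA", ALPHA_SYNUCLEIN_SEQUENCE, numbering_offset=1)

    v_y54h = VariantRecord("KRT8", 54, "Y", "H", "pathogenic", "bundled")
    v_g55a = VariantRecord("KRT8", 55, "G", "A", "pathogenic", "bundled")
    v_g62c = VariantRecord("KRT8", 62, "G", "C", "pathogenic", "bundled")
    fus_variants = [
        VariantRecord("FUS", 191, "G", "S", "pathogenic", "bundled"),
        VariantRecord("FUS", 225, "G", "V", "pathogenic", "bundled"),
        VariantRecord("FUS", 230, "G", "C", "pathogenic", "bundled"),
    ]
    hnrnpa2 = VariantRecord("HNRNPA2B1", 290, "D", "V", "pathogenic", "bundled")

    pairs = [
        SegmentPair("KRT8", 58, 64, "SGMGGIT", "SGMGCIT", v_g62c),
        SegmentPair("KRT8", 52, 58, "GGYGGAS", "GGYAGAS", v_g55a),
        # Y54H was characterised biochemically; no crystallised pair exists
        SegmentPair("KRT8", 52, 58, None, "GGHGGAS", v_y54h),
    ]

    deposited = [
        DepositedStructure("7K3C", "SGMGGIT", 7, "antiparallel"),
        DepositedStructure("7K3X", "SGMGCIT", 2, "parallel"),
        DepositedStructure("7K3Y", "GGYAGAS", 6, "antiparallel"),
    ]
    return FixtureBundle(
        krt8=krt8, alpha_synuclein=asyn, segment_pairs=pairs,
        variants=[v_y54h, v_g55a, v_g62c, *fus_variants, hnrnpa2],
        deposited=deposited)
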