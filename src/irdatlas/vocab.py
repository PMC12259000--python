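"""Closed vocabularies shared across the atlas pipeline.

Phenotype subsets follow the two-level clinical classification of inherited
retinal diseases (IRDs): 16 clinical subsets, each mapping to exactly one of
the two broad classes (non-syndromic: eye only; syndromic: eye plus other
organ systems). Multi-valued table cells use ";" as delimiter, so no label
may contain a semicolon or a tab.
"""

from __future__ import annotations

# -- phenotype classification ------------------------------------------------

NON_SYNDROMIC_SUBSETS: tuple[str, ...] = (
    "RP",        # retinitis pigmentosa
    "CD-CRD",    # cone dystrophy / cone-rod dystrophy / Stargardt disease
    "MD",        # macular dystrophy
    "LCA",       # Leber congenital amaurosis
    "OA",        # optic atrophy / optic nerve hypoplasia
    "CSNB",      # congenital stationary night blindness
    "EVR",       # exudative vitreoretinopathy / Norrie disease
    "CVD",       # color vision disorders (achromatopsia, color blindness)
    "other-nonsyndromic",
)

SYNDROMIC_SUBSETS: tuple[str, ...] = (
    "BBS",           # Bardet-Biedl syndrome
    "USH",           # Usher syndrome
    "Joubert",       # Joubert syndrome
    "SLS-NPHP",      # Senior-Loken syndrome / nephronophthisis
    "OCA",           # oculocutaneous albinism / foveal hypoplasia
    "syndromic-OA",  # syndromic optic atrophy
    "other-syndromic",
)

PHENOTYPE_SUBSETS: tuple[str, ...] = NON_SYNDROMIC_SUBSETS + SYNDROMIC_SUBSETS

NON_SYNDROMIC = "non-syndromic"
SYNDROMIC = "syndromic"
BROAD_CLASSES: tuple[str, ...] = (NON_SYNDROMIC, SYNDROMIC)

#: subset -> broad class; the broad classes of a gene are always *derived*
#: as the image of its phenotype subsets under this mapping, never stored.
SUBSET_BROAD_CLASS: dict[str, str] = {
    **{s: NON_SYNDROMIC for s in NON_SYNDROMIC_SUBSETS},
    **{s: SYNDROMIC for s in SYNDROMIC_SUBSETS},
}

# -- inheritance -------------------------------------------------------------

#: gene-level inheritance labels; "AD-AR" is itself a single label, not a
#: shorthand for {AD, AR}.
INHERITANCE_MODES: tuple[str, ...] = ("AR", "AD", "AD-AR", "X-linked", "mitochondrial")

# -- curation status ---------------------------------------------------------

STATUS_DISEASE = "disease"
STATUS_CANDIDATE = "candidate"
STATUS_EXCLUDED = "excluded"
GENE_STATUSES: tuple[str, ...] = (STATUS_DISEASE, STATUS_CANDIDATE, STATUS_EXCLUDED)

#: earliest year an IRD gene association was published (gyrate atrophy, OAT)
FIRST_DISCOVERY_YEAR = 1988

# -- variant vocabularies ----------------------------------------------------

CONSEQUENCES: tuple[str, ...] = (
    "canonical_splice",
    "stopgain",
    "frameshift_indel",
    "missense",
    "other",
)

#: loss-of-function consequence classes
LOF_CONSEQUENCES: frozenset[str] = frozenset(
    {"canonical_splice", "stopgain", "frameshift_indel"}
)

#: normalized clinical-significance labels treated as pathogenic/likely
#: pathogenic (PLP). Normalization: lowercase, "/" and " " replaced by "_".
PLP_SIGNIFICANCE: frozenset[str] = frozenset(
    {"pathogenic", "likely_pathogenic", "pathogenic_likely_pathogenic"}
)


def normalize_significance(raw: str) -> str:
    """Canonicalize a ClinVar clinical-significance string.

    ClinVar spells combined assertions inconsistently across releases
    ("Pathogenic/Likely_pathogenic", "Pathogenic, Likely pathogenic"); matching
    is case-insensitive after replacing "/", "," and " " with "_".
    """
    out = raw.strip().lower()
    for ch in ("/", ",", " "):
        out = out.replace(ch, "_")
    while "__" in out:
        out = out.replace("__", "_")
    return out.strip("_")


# -- functional categories ---------------------------------------------------

FUNCTIONAL_CATEGORIES: tuple[str, ...] = (
    "Cilium",
    "Cytoskeleton",
    "Transmembrane transport",
    "Lipid metabolism",
    "Visual cycle and phototransduction",
    "Mitochondria",
    "Nucleotide metabolism",
    "Melanosome",
    "Synaptic signaling",
    "Autophagic and endolysosomal pathway",
    "Extracellular matrix",
    "Cell adhesion",
    "Transcriptional regulation",
    "Retinal development",
    "RNA splicing and processing",
    "Protein folding and degradation",
    "Signal transduction",
    "DNA repair",
    "Glycosylation",
    "Ion channels",
)

#: fallback category for genes whose GO annotations map to none of the 20
OTHERS_CATEGORY = "Others"

ALL_CATEGORIES: tuple[str, ...] = FUNCTIONAL_CATEGORIES + (OTHERS_CATEGORY,)
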