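"""Duplex ddPCR assay definitions for noninvasive fetal blood-group genotyping.

Each assay is a duplex TaqMan reaction read on two fluorescence channels:
FAM (blue) and HEX/VIC (green).  For the SNP assays (*RHCE* rs676785 C/c,
*RHCE* rs609320 E/e, *KEL* rs8176058 KEL1/KEL2) each channel detects one
allele.  The *RHD* assay is special: RhD-negative Europeans almost always
carry a whole-gene deletion, so the FAM channel detects *RHD* exon 7
(presence of the gene) while the HEX channel carries a β-globin probe that
counts total cell-free DNA genomes rather than a polymorphic allele.

The analysis model assumes the mother is homozygous at the assay locus.
Any positive droplet on the channel of the allele she lacks can then only
come from fetal DNA (or from the false-positive background), which is what
makes fetal genotyping from maternal plasma possible with this design.
"""

from __future__ import annotations

import enum
import io as _io
import os
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

__all__ = [
    "AssayConfigError",
    "AssumptionViolationError",
    "Channel",
    "AssayDefinition",
    "MaternalContext",
    "builtin_registry",
    "load_assays",
    "parse_genotype",
    "fetus_specific_channel",
    "maternal_channel",
]


class AssayConfigError(ValueError):
    """Raised for malformed or inconsistent assay registry entries."""


class AssumptionViolationError(ValueError):
    """Raised when an input violates the homozygous-mother analysis model."""


class Channel(str, enum.Enum):
    """Fluorescence channel of a duplex ddPCR reaction."""

    FAM = "FAM"  # blue; channel 1 in amplitude tables
    HEX = "HEX"  # green (HEX/VIC); channel 2 in amplitude tables

    def other(self) -> "Channel":
        return Channel.HEX if self is Channel.FAM else Channel.FAM


#: Unicode minus / en-dash variants that appear in genotype strings.
_DASHES = {"−": "-", "–": "-", "—": "-"}


def _normalise_allele(label: str) -> str:
    out = label.strip()
    for bad, good in _DASHES.items():
        out = out.replace(bad, good)
    return out


@dataclass(frozen=True)
class AssayDefinition:
    """One duplex assay: which allele each channel detects.

    Parameters
    ----------
    name
        Registry identifier, e.g. ``"RHD_ex7"``.
    gene
        Gene symbol (*RHD*, *RHCE*, *KEL*).
    snp_id
        dbSNP rs identifier, or ``"deletion"`` for the RHD presence/absence
        assay.
    fam_allele, hex_allele
        Allele label detected on each channel.  For a total-DNA reference
        channel the label names the control locus (``"beta-globin"``).
    amplicon_length_bp
        PCR product length; annotation only.
    reference_channel_is_total_dna
        True when the HEX channel is a non-polymorphic total-DNA control
        (the RHD assay).  Downstream quantification must then treat the HEX
        count as total (maternal + fetal) genomes.
    null_allele
        Label of the null allele for presence/absence assays
        (``"RHD-"``); None for SNP assays.
    metadata
        Inert annotation (primer/probe sequences etc.); never computed on.
    """

    name: str
    gene: str
    snp_id: str
    fam_allele: str
    hex_allele: str
    amplicon_length_bp: int
    reference_channel_is_total_dna: bool = False
    null_allele: str | None = None
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise AssayConfigError("assay 'name' must be non-empty")
        if self.fam_allele == self.hex_allele:
            raise AssayConfigError(
                f"assay {self.name!r}: fam_allele and hex_allele must differ "
                f"(both {self.fam_allele!r})"
            )
        if self.amplicon_length_bp <= 0:
            raise AssayConfigError(
                f"assay {self.name!r}: amplicon_length_bp must be positive"
            )
        if self.reference_channel_is_total_dna and self.null_allele is None:
            raise AssayConfigError(
                f"assay {self.name!r}: a total-DNA reference channel requires "
                "a null_allele (presence/absence assay)"
            )

    @property
    def genotype_alleles(self) -> tuple[str, ...]:
        """Allele labels a maternal or fetal genotype may carry."""
        if self.reference_channel_is_total_dna:
            return (self.fam_allele, self.null_allele)  # type: ignore[return-value]
        alleles = [self.fam_allele, self.hex_allele]
        if self.null_allele is not None:
            alleles.append(self.null_allele)
        return tuple(alleles)

    def channel_of(self, allele: str) -> Channel | None:
        """Channel that detects *allele*; None for a null allele."""
        if allele == self.fam_allele:
            return Channel.FAM
        if allele == self.hex_allele and not self.reference_channel_is_total_dna:
            return Channel.HEX
        if allele == self.null_allele:
            return None
        raise AssayConfigError(
            f"allele {allele!r} is not part of assay {self.name!r} "
            f"(known: {self.genotype_alleles})"
        )


def parse_genotype(assay: AssayDefinition, text: str | tuple[str, str]) -> tuple[str, str]:
    """Parse a genotype string into an allele pair for *assay*.

    Accepts slash-separated pairs (``"KEL2/KEL2"``, ``"RHD-/RHD-"``) and
    concatenated short forms (``"cc"``, ``"Ee"``).  Unicode minus signs are
    normalised to ASCII.
    """
    if isinstance(text, tuple):
        pair = tuple(_normalise_allele(a) for a in text)
    else:
        s = _normalise_allele(text)
        if "/" in s:
            parts = s.split("/")
            if len(parts) != 2:
                raise AssumptionViolationError(
                    f"genotype {text!r} must contain exactly two alleles"
                )
            pair = (parts[0].strip(), parts[1].strip())
        else:
            pair = _split_concatenated(assay, s)
    for allele in pair:
        if allele not in assay.genotype_alleles:
            raise AssumptionViolationError(
                f"allele {allele!r} is not valid for assay {assay.name!r} "
                f"(known: {assay.genotype_alleles})"
            )
    return pair  # type: ignore[return-value]


def _split_concatenated(assay: AssayDefinition, s: str) -> tuple[str, str]:
    # longest-first so "KEL1KEL2" splits before single letters would
    for first in sorted(assay.genotype_alleles, key=len, reverse=True):
        if s.startswith(first) and s[len(first):] in assay.genotype_alleles:
            return (first, s[len(first):])
    raise AssumptionViolationError(
        f"cannot parse genotype {s!r} for assay {assay.name!r} "
        f"(known alleles: {assay.genotype_alleles})"
    )


@dataclass(frozen=True)
class MaternalContext:
    """A sample's analysis context: one assay plus the maternal genotype.

    The maternal genotype must be homozygous — that is the core assumption
    of the method, and heterozygous mothers are rejected here rather than
    silently producing meaningless fetal calls.  For the RHD assay only an
    RHD−/RHD− mother is a valid context: against an RHD+ maternal
    background the fetal RHD signal is indistinguishable from the mother's.
    """

    assay: AssayDefinition
    maternal_genotype: tuple[str, str]

    def __init__(self, assay: AssayDefinition, maternal_genotype) -> None:
        pair = parse_genotype(assay, maternal_genotype)
        object.__setattr__(self, "assay", assay)
        object.__setattr__(self, "maternal_genotype", pair)
        if pair[0] != pair[1]:
            raise AssumptionViolationError(
                f"maternal genotype {pair} is heterozygous; the analysis "
                "requires a homozygous mother"
            )
        if assay.reference_channel_is_total_dna and pair[0] != assay.null_allele:
            raise AssumptionViolationError(
                f"assay {assay.name!r}: only a {assay.null_allele}/"
                f"{assay.null_allele} mother is analysable — fetal "
                f"{assay.fam_allele} cannot be distinguished in an "
                f"{assay.fam_allele} maternal background"
            )

    @property
    def maternal_allele(self) -> str:
        return self.maternal_genotype[0]

    def format_genotype(self, pair: tuple[str, str] | None = None) -> str:
        pair = self.maternal_genotype if pair is None else pair
        return "/".join(pair)


def fetus_specific_channel(ctx: MaternalContext) -> tuple[Channel, str]:
    """Channel (and allele) whose positives can only be fetal or noise.

    For a homozygous mother the fetus-specific channel is the one detecting
    the allele she lacks; for the RHD deletion assay it is the FAM (*RHD*
    exon 7) channel, since the RHD−/RHD− mother contributes no RHD
    molecules at all.
    """
    assay = ctx.assay
    if assay.reference_channel_is_total_dna:
        return Channel.FAM, assay.fam_allele
    if ctx.maternal_allele == assay.fam_allele:
        return Channel.HEX, assay.hex_allele
    return Channel.FAM, assay.fam_allele


def maternal_channel(ctx: MaternalContext) -> Channel:
    """The maternal/reference channel (β-globin for the RHD assay)."""
    return fetus_specific_channel(ctx)[0].other()


def builtin_registry() -> dict[str, AssayDefinition]:
    """The four validated duplex assays, available without any config file."""
    return {a.name: a for a in _BUILTIN_ASSAYS}


_BUILTIN_ASSAYS = (
    AssayDefinition(
        name="RHD_ex7",
        gene="RHD",
        snp_id="deletion",
        fam_allele="RHD+",
        hex_allele="beta-globin",
        amplicon_length_bp=72,
        reference_channel_is_total_dna=True,
        null_allele="RHD-",
        metadata={
            "fam_target": "RHD exon 7",
            "hex_target": "beta-globin total cfDNA control (74 bp amplicon)",
            "fam_primer_f": "GGGTGTTGTAACCGAGTGCTG",
            "fam_primer_r": "CTCCAAGCAGACCCAGCAAG",
            "annealing_c": 55,
        },
    ),
    AssayDefinition(
        name="RHCE_rs609320",
        gene="RHCE",
        snp_id="rs609320",
        fam_allele="e",
        hex_allele="E",
        amplicon_length_bp=64,
        metadata={
            "variant": "c.676G>C (Pro226Ala), E/e antigen",
            "primer_f": "ATTCTTCCTTTGGATTGGAC",
            "primer_r": "CTTGTGGATGTTCTGGC",
            "annealing_c": 55,
        },
    ),
    AssayDefinition(
        name="RHCE_rs676785",
        gene="RHCE",
        snp_id="rs676785",
        fam_allele="c",
        hex_allele="C",
        amplicon_length_bp=74,
        metadata={
            "variant": "c.307G>A (Ser103Pro), C/c antigen",
            "primer_f": "AATACCTGAACAGTGTGATG",
            "primer_r": "CTGCTGGACGGCTTC",
            "annealing_c": 55,
            "note": "FAM (c) channel may need a manual amplitude cut-off",
        },
    ),
    AssayDefinition(
        name="KEL_rs8176058",
        gene="KEL",
        snp_id="rs8176058",
        fam_allele="KEL1",
        hex_allele="KEL2",
        amplicon_length_bp=65,
        metadata={
            "variant": "c.578C>T (Thr193Met), K/k antigen",
            "commercial_assay": "ddPCR Mutation Assay KEL p.T193M",
            "annealing_c": 55,
        },
    ),
)

_REQUIRED_FIELDS = (
    "name",
    "gene",
    "snp_id",
    "fam_allele",
    "hex_allele",
    "amplicon_length_bp",
)


def load_assays(config_source=None) -> dict[str, AssayDefinition]:
    """Load the assay registry, optionally extended from a config document.

    Parameters
    ----------
    config_source
        None (built-ins only), a mapping with an ``assays`` list, a YAML/JSON
        file path, or an open text stream.

    Returns
    -------
    dict mapping assay name to :class:`AssayDefinition`.  The four built-in
    assays are always present; configured entries may not reuse their names.
    """
    registry = builtin_registry()
    if config_source is None:
        return registry

    if isinstance(config_source, Mapping):
        doc = dict(config_source)
    elif isinstance(config_source, (str, os.PathLike)):
        with open(config_source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    elif isinstance(config_source, _io.TextIOBase) or hasattr(config_source, "read"):
        doc = yaml.safe_load(config_source)
    else:
        raise AssayConfigError(
            f"unsupported assay config source: {type(config_source).__name__}"
        )

    if not isinstance(doc, Mapping) or "assays" not in doc:
        raise AssayConfigError("assay config must be a mapping with an 'assays' list")
    entries = doc["assays"]
    if not isinstance(entries, (list, tuple)):
        raise AssayConfigError("'assays' must be a list of assay entries")

    for i, entry in enumerate(entries):
        if not isinstance(entry, Mapping):
            raise AssayConfigError(f"assay entry #{i} is not a mapping")
        missing = [f for f in _REQUIRED_FIELDS if f not in entry]
        if missing:
            raise AssayConfigError(
                f"assay entry #{i} ({entry.get('name', '?')!r}) is missing "
                f"required field(s): {', '.join(missing)}"
            )
        known = set(_REQUIRED_FIELDS) | {
            "reference_channel_is_total_dna",
            "null_allele",
            "metadata",
        }
        unknown = set(entry) - known
        if unknown:
            raise AssayConfigError(
                f"assay entry #{i} has unknown field(s): {sorted(unknown)}"
            )
        assay = AssayDefinition(**{k: entry[k] for k in entry})
        if assay.name in registry:
            raise AssayConfigError(f"duplicate assay name {assay.name!r}")
        registry[assay.name] = assay
    return registry
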