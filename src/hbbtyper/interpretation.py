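"""Clinical interpretation: from classified alleles to a diagnosis label.

The rule cascade encodes standard haemoglobinopathy genetics: homozygous
βS is sickle cell disease, a lone βS carrier is sickle cell trait, one or
two β-thalassaemia alleles give trait or homozygous thalassaemia, and a
βS allele co-occurring with a β-thal allele is a compound heterozygote —
but only when read-backed phasing shows the two alternates in *trans*;
in *cis* they sit on one chromosome (an unusual complex allele), and
without a confident phase the engine refuses to guess and flags the
sample for review.  Ambiguous zygosity anywhere likewise forces review:
the engine never emits a definitive disease label from uncertain input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .annotation import Annotation
from .phasing import PhaseCall
from .variant_caller import VariantCall

__all__ = [
    "ClassifiedCall",
    "SampleGenotype",
    "Diagnosis",
    "DIAGNOSIS_LABELS",
    "diagnose",
    "concordance",
    "DEFAULT_LABEL_MAP",
]

DIAGNOSIS_LABELS = (
    "normal",
    "sickle_cell_trait",
    "sickle_cell_disease",
    "beta_thal_trait",
    "beta_thal_homozygous",
    "hbs_beta_thal_compound_het",
    "complex_cis",
    "needs_review",
)

_THAL_CLASSES = ("beta_zero", "beta_plus")


@dataclass(frozen=True)
class ClassifiedCall:
    call: VariantCall
    annotation: Annotation
    allele_class: str  # beta_S | beta_zero | beta_plus | benign | VUS
    catalogued: bool = True


@dataclass
class SampleGenotype:
    sample_id: str
    classified_calls: list[ClassifiedCall] = field(default_factory=list)
    phases: list[PhaseCall] = field(default_factory=list)


@dataclass(frozen=True)
class Diagnosis:
    sample_id: str
    label: str
    rationale: str
    contributing_variants: tuple[str, ...] = ()


def _allele_count(zygosity: str) -> int:
    return {"het": 1, "hom": 2}.get(zygosity, 0)


def _phase_between(geno: SampleGenotype, a: VariantCall, b: VariantCall) -> str:
    for ph in geno.phases:
        pair = {ph.var_a.gpos, ph.var_b.gpos}
        if pair == {a.gpos, b.gpos}:
            return ph.configuration
    return "unphased"


def diagnose(genotype: SampleGenotype) -> Diagnosis:
    """Pure rule cascade from classified PASS calls and phase verdicts."""
    sid = genotype.sample_id

    # conservative gates first: any ambiguity on a clinically relevant
    # allele blocks a definitive label.
    for cc in genotype.classified_calls:
        if cc.allele_class == "benign":
            continue
        if cc.call.zygosity == "ambiguous" or not cc.call.is_pass:
            return Diagnosis(
                sid, "needs_review",
                f"{cc.annotation.hgvs_c}: zygosity/filter not definitive "
                f"(VAF {cc.call.vaf:.2f}, filter {cc.call.filter})",
                (cc.annotation.hgvs_c,),
            )
        if cc.allele_class == "VUS":
            return Diagnosis(
                sid, "needs_review",
                f"{cc.annotation.hgvs_c}: uncatalogued missense of uncertain significance",
                (cc.annotation.hgvs_c,),
            )

    s_calls = [cc for cc in genotype.classified_calls if cc.allele_class == "beta_S"]
    t_calls = [cc for cc in genotype.classified_calls
               if cc.allele_class in _THAL_CLASSES]
    s = sum(_allele_count(cc.call.zygosity) for cc in s_calls)
    t = sum(_allele_count(cc.call.zygosity) for cc in t_calls)
    variants = tuple(cc.annotation.hgvs_c for cc in s_calls + t_calls)

    if s == 0 and t == 0:
        return Diagnosis(sid, "normal", "no pathogenic beta-globin allele", ())
    if s >= 2:
        return Diagnosis(sid, "sickle_cell_disease", "homozygous beta-S", variants)
    if s == 1 and t == 0:
        return Diagnosis(sid, "sickle_cell_trait", "single beta-S allele", variants)
    if s == 0 and t == 1:
        cls = t_calls[0].allele_class
        return Diagnosis(sid, "beta_thal_trait",
                         f"single {cls} thalassaemia allele", variants)
    if s == 0 and t >= 2:
        return Diagnosis(sid, "beta_thal_homozygous",
                         "two beta-thalassaemia alleles", variants)

    # s == 1 and t >= 1: compound configuration decided by phase
    phase = _phase_between(genotype, s_calls[0].call, t_calls[0].call)
    if phase == "trans":
        return Diagnosis(
            sid, "hbs_beta_thal_compound_het",
            "beta-S in trans with a beta-thalassaemia allele", variants,
        )
    if phase == "cis":
        return Diagnosis(
            sid, "complex_cis",
            "beta-S in cis with a beta-thalassaemia allele (single complex allele)",
            variants,
        )
    return Diagnosis(
        sid, "needs_review",
        "beta-S with a beta-thalassaemia allele but no confident phase", variants,
    )


# ----------------------------------------------------------------------
# concordance against printed standard-test labels
# ----------------------------------------------------------------------

#: engine label -> normalized printed labels treated as concordant.
DEFAULT_LABEL_MAP: dict[str, tuple[str, ...]] = {
    "normal": ("normal",),
    "sickle_cell_trait": ("sickle cell heterozygote", "sickle cell trait"),
    "sickle_cell_disease": ("sickle cell disease",),
    "beta_thal_trait": (
        "beta+ thal heterozygote",
        "beta thal heterozygote",
        "beta+ thalassaemia heterozygote",
    ),
    "beta_thal_homozygous": (
        "beta+ thal intermedia",
        "beta thal intermedia",
        "beta thal homozygote",
    ),
    "hbs_beta_thal_compound_het": (
        "beta+ thal, sickle cell heterozygote",
        "sickle cell, beta+ thal heterozygote",
        "hbs/beta thal compound heterozygote",
    ),
}


def normalize_label(label: str) -> str:
    s = label.lower().replace("^", "").replace("β", "beta")
    s = re.sub(r"\s+", " ", s).strip().rstrip(".")
    return s


def concordance(
    diagnoses: list[Diagnosis],
    reference_labels: dict[str, str],
    label_map: dict[str, tuple[str, ...]] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Fraction of samples whose engine diagnosis maps onto the printed
    standard-test label, plus a per-sample concordance table."""
    if not diagnoses:
        raise ValueError("no diagnoses to compare")
    label_map = label_map if label_map is not None else DEFAULT_LABEL_MAP
    rows = []
    for dx in diagnoses:
        if dx.sample_id not in reference_labels:
            raise KeyError(f"no reference label for sample {dx.sample_id}")
        ref = normalize_label(reference_labels[dx.sample_id])
        accepted = tuple(normalize_label(x) for x in label_map.get(dx.label, ()))
        rows.append(
            {
                "sample_id": dx.sample_id,
                "engine_label": dx.label,
                "reference_label": reference_labels[dx.sample_id],
                "concordant": ref in accepted,
            }
        )
    table = pd.DataFrame(rows)
    return float(table["concordant"].mean()), table
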