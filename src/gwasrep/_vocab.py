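"""Shared controlled vocabularies and sentinels.

The disease areas are the ten most burdensome non-communicable causes of
death in the Global Burden of Disease 2019 ranking (with the heterogeneous
"other NCDs" bucket dropped in favour of mental disorders), plus the pooled
``all_traits`` category that every mapped study joins exactly once.
"""

from __future__ import annotations

# Missingness marker used by the GWAS Catalog ancestry download.  It is a
# first-class value, distinguishable from an empty field: "Not Reported"
# rows exist and are counted, then excluded from proportion denominators.
NOT_REPORTED = "NOT_REPORTED"

# Resolution failure marker for affiliations (institution/country/income).
# Kept as a reportable category so proportion tables still sum to one.
UNRESOLVED = "UNRESOLVED"

ALL_TRAITS = "all_traits"

DISEASE_AREAS = (
    "cardiovascular diseases",
    "neoplasms",
    "chronic respiratory diseases",
    "diabetes and CKD",
    "neurological disorders",
    "mental disorders",
    "digestive diseases",
    "musculoskeletal disorders",
    "substance use",
    "skin diseases",
)

# Broad ancestral categories as used by the Catalog's ancestry file.
BROAD_ANCESTRY_CATEGORIES = (
    "European",
    "East Asian",
    "South Asian",
    "South East Asian",
    "Central Asian",
    "African American or Afro-Caribbean",
    "African unspecified",
    "Sub-Saharan African",
    "Hispanic or Latin American",
    "Greater Middle Eastern (Middle Eastern, North African or Persian)",
    "Native American",
    "Oceanian",
    "Aboriginal Australian",
    "Circumpolar peoples",
    "Asian unspecified",
    "Other admixed ancestry",
)

INCOME_GROUPS = ("HIC", "UMIC", "LMIC", "LIC")

AUTHOR_CATEGORIES = ("all", "first", "senior")

GENDER_LABELS = ("men", "women", "unknown")

STAGES = ("discovery", "replication")
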