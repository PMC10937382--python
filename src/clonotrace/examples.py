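"""Packaged worked example: a 33-construct bladder-urothelial pool and the
three-clone tumour with papillary / squamous / sarcomatoid regions.

The tumour reproduces the structure of the published worked example: four
events (Ywhaz, Pik3ca E545K, Pparg, Pvrl4) common to all three dominant
clones, and three events (Fgfr3 S243C, shAtm, Zfp703) private to the clone
that seeded the papillary urothelial carcinoma region.  The other two clones
each carry one additional private event so the three barcode combinations
are distinguishable.  Everything is generated programmatically from a fixed
design seed, so the example is reproducible and ships no data files.
"""

from __future__ import annotations

from .models import PoolModel, TumorModel
from .simulate import simulate_library, tumor_from_spec

# gain-of-function (ORF) and knockdown (shRNA) payloads of the example pool
ORF_GENES = [
    "Fgfr3_S243C",
    "Pik3ca_E545K",
    "Ywhaz",
    "Pparg",
    "Pvrl4",
    "Zfp703",
    "Ccnd1",
    "E2f3",
    "Erbb2",
    "Yap1",
    "Sox4",
    "Mdm2",
    "Ccne1",
    "Egfr",
]
SHRNA_GENES = [
    "shAtm",
    "shTrp53",
    "shPten",
    "shRb1",
    "shKdm6a",
    "shKmt2d",
    "shArid1a",
    "shStag2",
    "shEp300",
    "shCrebbp",
    "shFbxw7",
    "shTsc1",
    "shCdkn1a",
    "shCdkn2a",
    "shNf1",
    "shSpen",
    "shElf3",
    "shRhoa",
    "shAsxl2",
]

COMMON_EVENTS = ["Ywhaz", "Pik3ca_E545K", "Pparg", "Pvrl4"]
PAPILLARY_PRIVATE_EVENTS = ["Fgfr3_S243C", "shAtm", "Zfp703"]

HISTOLOGY_PAPILLARY = "papillary urothelial carcinoma"
HISTOLOGY_SQUAMOUS = "urothelial carcinoma with squamous differentiation"
HISTOLOGY_SARCOMATOID = "sarcomatoid urothelial carcinoma"

_DESIGN_SEED = 20230433  # fixed barcode-design seed of the packaged pool


def example_pool(class_imbalance: float = 1.0) -> PoolModel:
    """The 33-construct example pool (14 ORF + 19 shRNA constructs).

    ``class_imbalance`` sets the fold-overrepresentation of shRNA titers
    (1 = the rebalanced pool; ~10 = a freshly pooled library)."""
    return simulate_library(
        n_orf=len(ORF_GENES),
        n_shrna=len(SHRNA_GENES),
        class_imbalance=class_imbalance,
        seed=_DESIGN_SEED,
        orf_genes=ORF_GENES,
        shrna_genes=SHRNA_GENES,
    )


def papillary_tumor_example() -> TumorModel:
    """Three dominant clones sharing four events; the papillary clone adds
    three private events; one pure region per histology."""
    common = list(COMMON_EVENTS)
    clones = [
        ("cloneA", common + PAPILLARY_PRIVATE_EVENTS, 0.45, HISTOLOGY_PAPILLARY),
        ("cloneB", common + ["shTrp53"], 0.32, HISTOLOGY_SQUAMOUS),
        ("cloneC", common + ["shPten"], 0.23, HISTOLOGY_SARCOMATOID),
    ]
    regions = [
        ("region_papillary", HISTOLOGY_PAPILLARY, {"cloneA": 1.0}),
        ("region_squamous", HISTOLOGY_SQUAMOUS, {"cloneB": 1.0}),
        ("region_sarcomatoid", HISTOLOGY_SARCOMATOID, {"cloneC": 1.0}),
    ]
    return tumor_from_spec(clones, regions)
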