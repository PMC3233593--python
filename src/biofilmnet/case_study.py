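"""Published co-occurrence fixture for the Tannerella sp. OT286 case study.

The oral phylotype *Tannerella* sp. OT286 (clone BU063) is uncultivated but
repeatedly detected in periodontally healthy sites. The published HOMIM
module analysis reported which species shared a module with OT286 in each
of four sample clusters (two from healthy, two from diseased biofilms);
those membership lists are reproduced here as a small worked-example
fixture for :func:`biofilmnet.helpers.candidate_helpers`. Oral taxon (OT)
numbers follow the Human Oral Microbiome Database nomenclature.
"""

from __future__ import annotations

import pandas as pd

from biofilmnet.modules import ModulePartition

TARGET = "Tannerella sp. OT286"

#: species sharing the target's module, per sample cluster
CO_OCCURRENCE: dict[str, list[str]] = {
    "healthy_cluster_1": [
        "Bacteroidetes sp. OT274",
        "Campylobacter gracilis OT623",
        "Dialister invisus OT118",
        "Parvimonas micros OT111",
        "Prevotella sp. OT317 OT472 OT658",
        "Prevotella sp. OT658 OT693 OT714 OT782",
        "Prevotella nigrescens OT693",
        "Prevotella oris OT311",
        "Prevotella tannerae OT466",
        "Streptococcus sp. OT768 OT767 OT758 OT755 OT745 OT734 OT728 OT721 OT707",
        "Streptococcus intermedius and anginosus OT543 OT644",
        "Streptococcus intermedius and constellatus OT576 OT644",
        "Streptococcus mitis OT069 OT398",
    ],
    "healthy_cluster_2": [
        "Bacteroidetes sp. OT274",
        "Campylobacter gracilis OT623",
        "Dialister invisus OT118",
        "Parvimonas micros OT111",
        "Prevotella sp. OT317 OT472 OT658",
        "Prevotella sp. OT658 OT693 OT714 OT782",
        "Prevotella nigrescens OT693",
        "Prevotella oris OT311",
        "Prevotella tannerae OT466",
        "Streptococcus sp. OT768 OT767 OT758 OT755 OT745 OT734 OT728 OT721 OT707",
        "Streptococcus intermedius and anginosus OT543 OT644",
        "Streptococcus intermedius and constellatus OT576 OT644",
        "Streptococcus mitis OT069 OT398",
    ],
    "diseased_cluster_1": [
        "Bacteroidetes sp. OT274",
        "Prevotella sp. OT317 OT472 OT658",
        "Prevotella sp. OT658 OT693 OT714 OT782",
        "Prevotella nigrescens OT693",
        "Prevotella tannerae OT466",
        "Streptococcus mitis OT069 OT398",
    ],
    "diseased_cluster_2": [
        "Bacteroidetes sp. OT274",
        "Prevotella sp. OT317 OT472 OT658",
        "Prevotella sp. OT658 OT693 OT714 OT782",
        "Prevotella nigrescens OT693",
        "Prevotella tannerae OT466",
        "Streptococcus mitis OT069 OT398",
    ],
}

#: cultivability per taxon; OT274 is an uncultivated Bacteroidetes phylotype
CULTIVABILITY: dict[str, bool] = {
    "Bacteroidetes sp. OT274": False,
    "Campylobacter gracilis OT623": True,
    "Dialister invisus OT118": True,
    "Parvimonas micros OT111": True,
    "Prevotella sp. OT317 OT472 OT658": True,
    "Prevotella sp. OT658 OT693 OT714 OT782": True,
    "Prevotella nigrescens OT693": True,
    "Prevotella oris OT311": True,
    "Prevotella tannerae OT466": True,
    "Streptococcus sp. OT768 OT767 OT758 OT755 OT745 OT734 OT728 OT721 OT707": True,
    "Streptococcus intermedius and anginosus OT543 OT644": True,
    "Streptococcus intermedius and constellatus OT576 OT644": True,
    "Streptococcus mitis OT069 OT398": True,
    TARGET: False,
}


def case_study_partitions(
    clusters: list[str] | None = None,
) -> dict[str, ModulePartition]:
    """Module partitions encoding the published co-occurrence lists.

    In each requested sample cluster the target and its listed co-occurring
    species share one module color; every species listed in any other
    cluster but not this one is placed in a different color, so that
    "shares the target's module" reproduces the published lists exactly.
    """
    if clusters is None:
        clusters = list(CO_OCCURRENCE)
    all_taxa = sorted({t for lst in CO_OCCURRENCE.values() for t in lst} | {TARGET})
    parts: dict[str, ModulePartition] = {}
    for cluster in clusters:
        mates = set(CO_OCCURRENCE[cluster])
        colors = pd.Series(
            ["with_target" if (t in mates or t == TARGET) else "elsewhere"
             for t in all_taxa],
            index=all_taxa,
            name="module",
        )
        parts[cluster] = ModulePartition(colors=colors)
    return parts
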