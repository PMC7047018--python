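"""Species constants for the eleven-taxon grass panel.

Eight species have published reference genomes and enter the analysis as
annotated CDS sets joined through a syntenic-ortholog table anchored on
sorghum; three C3 panicoid species (Dichanthelium, Chasmanthium,
Hymenachne) are represented only by long-read consensus transcripts.
Rice and brachypodium form the BOP-clade outgroup to the PACMAD taxa.
The maize-like (Zea) and teff-like (Eragrostis) lineages carry independent
whole-genome duplications, so their syntenic cells may hold retained
duplicate gene pairs.
"""

from __future__ import annotations

# literature consensus topology over the eleven taxa, outgroup pair first
SPECIES_TOPOLOGY = (
    "((Oryza,Brachypodium),((Oropetium,Eragrostis),(Chasmanthium,"
    "((Dichanthelium,(Pennisetum,Setaria)),(Hymenachne,(Sorghum,Zea))))));"
)

OUTGROUP = frozenset({"Oryza", "Brachypodium"})

REFERENCE_SPECIES = (
    "Oryza", "Brachypodium", "Oropetium", "Eragrostis",
    "Pennisetum", "Setaria", "Sorghum", "Zea",
)
TARGET_SPECIES = ("Dichanthelium", "Chasmanthium", "Hymenachne")
ALL_SPECIES = REFERENCE_SPECIES + TARGET_SPECIES

ANCHOR_SPECIES = "Sorghum"

# WGD lineage name -> species carrying the duplication
WGD_LINEAGES = {"maize_like": "Zea", "teff_like": "Eragrostis"}

# fraction of syntenic genes retained as duplicate pairs after fractionation
DEFAULT_RETENTION = {"maize_like": 0.30, "teff_like": 0.91}

MISSING_CELL = "."
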