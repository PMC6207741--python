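"""Published reference inputs for the Phacaceae comparative analysis.

These are the printed per-genome characteristics of the nine Phacaceae
plastomes (eight newly deposited, MH898667-MH898674, plus the earlier
Phacus orbicularis deposit KR921747), the Euglenophyta species-tree topology
used for character mapping, the inverted-repeat presence states of its tips,
and the maturase complements reported for the Phacaceae.  They serve as
package inputs — the pipeline recomputes every derived column from the raw
counts rather than trusting the printed ratios.
"""

from __future__ import annotations

import pandas as pd

from .character_evolution import read_newick
from .model import BinaryCharacter

#: taxon, accession, size (bp), size is a lower bound, IR copies, G+C %,
#: PCGs, avg PCG length (bp, intron space included), tRNAs, rRNAs,
#: introns, introns/PCG, PCGs with introns, % PCGs with introns
PHACACEAE_TABLE_COLUMNS = (
    "taxon", "accession", "size_bp", "size_is_lower_bound", "n_ir_copies",
    "gc_percent", "n_pcg", "avg_pcg_len", "n_trna", "n_rrna", "n_introns",
    "introns_per_pcg", "n_pcg_with_introns", "pct_pcg_with_introns")

PHACACEAE_TABLE_ROWS = (
    ("Discoplastis_spathirhyncha", "MH898670", 83936, True, 2, 29.3, 61,
     1126.6, 29, 6, 59, 0.97, 31, 50.8),
    ("Lepocinclis_ovum", "MH898674", 69550, True, 2, 30.3, 62,
     884.4, 28, 4, 50, 0.81, 23, 37.1),
    ("Lepocinclis_playfairiana", "MH898671", 77415, True, 2, 31.9, 62,
     993.5, 29, 4, 79, 1.27, 33, 53.2),
    ("Lepocinclis_steinii", "MH898672", 81836, True, 2, 22.7, 63,
     1085.0, 29, 6, 81, 1.29, 35, 55.5),
    ("Lepocinclis_tripteris_MI", "MH898668", 81048, True, 2, 27.3, 62,
     1013.6, 29, 6, 94, 1.52, 39, 62.9),
    ("Lepocinclis_tripteris_UTEX", "MH898669", 82966, True, 2, 27.4, 62,
     1014.6, 29, 6, 95, 1.53, 39, 62.9),
    ("Phacus_inflexus", "MH898667", 58112, False, 1, 29.4, 60,
     531.3, 27, 3, 29, 0.48, 16, 26.7),
    ("Phacus_orbicularis", "KR921747", 66418, True, 1, 27.2, 61,
     872.9, 27, 3, 67, 1.10, 34, 55.7),
    ("Phacus_pleuronectes", "MH898673", 90869, False, 1, 24.6, 63,
     1295.6, 27, 3, 104, 1.65, 38, 60.3),
)

#: the eight newly deposited genomes (P. orbicularis excluded)
NEW_PHACACEAE = tuple(r[0] for r in PHACACEAE_TABLE_ROWS
                      if r[1].startswith("MH"))

#: maturase complements of the new Phacaceae genomes: mat1 is universal;
#: mat2 is missing from P. inflexus and both L. tripteris strains; mat5 is
#: carried only by both L. tripteris strains and P. pleuronectes.
PHACACEAE_MATURASES: dict[str, tuple[str, ...]] = {
    "Discoplastis_spathirhyncha": ("mat1", "mat2"),
    "Lepocinclis_ovum": ("mat1", "mat2"),
    "Lepocinclis_playfairiana": ("mat1", "mat2"),
    "Lepocinclis_steinii": ("mat1", "mat2"),
    "Lepocinclis_tripteris_MI": ("mat1", "mat5"),
    "Lepocinclis_tripteris_UTEX": ("mat1", "mat5"),
    "Phacus_inflexus": ("mat1",),
    "Phacus_pleuronectes": ("mat1", "mat2", "mat5"),
}

#: Euglenophyta species-tree topology used for loss mapping: Eutreptiales
#: (Eutreptia sister to the two Eutreptiella) sister to Euglenales, inside
#: which the Euglenaceae clade is sister to the Phacaceae, where
#: Discoplastis branches first and Lepocinclis and Phacus are sister clades.
EUGLENOPHYTA_TREE_NEWICK = (
    "((Eutreptia_viridis,(Eutreptiella_gymnastica,Eutreptiella_pomquetensis))"
    "Eutreptiales,"
    "((((Euglena_gracilis,Euglena_viridis),Euglena_agilis),"
    "(((Colacium_vesiculosum,Strombomonas_acuminata),Trachelomonas_volvocina),"
    "((Monomorphina_aenigmatica,Cryptoglena_skujae),Euglenaria_anabaena)))"
    "Euglenaceae,"
    "(Discoplastis_spathirhyncha,"
    "((((Lepocinclis_tripteris_MI,Lepocinclis_tripteris_UTEX),"
    "Lepocinclis_steinii),(Lepocinclis_playfairiana,Lepocinclis_ovum)),"
    "(Phacus_inflexus,(Phacus_orbicularis,Phacus_pleuronectes))Phacus))"
    "Phacaceae)Euglenales)Euglenophyta;"
)

#: inverted-repeat presence at the tips: the quadripartite arrangement is
#: retained by both Eutreptiella species and by Discoplastis and all
#: Lepocinclis; it is absent from Eutreptia, every Phacus and the whole
#: Euglenaceae clade.
IR_PRESENCE: dict[str, str] = {
    "Eutreptia_viridis": "0",
    "Eutreptiella_gymnastica": "1",
    "Eutreptiella_pomquetensis": "1",
    "Euglena_gracilis": "0",
    "Euglena_viridis": "0",
    "Euglena_agilis": "0",
    "Colacium_vesiculosum": "0",
    "Strombomonas_acuminata": "0",
    "Trachelomonas_volvocina": "0",
    "Monomorphina_aenigmatica": "0",
    "Cryptoglena_skujae": "0",
    "Euglenaria_anabaena": "0",
    "Discoplastis_spathirhyncha": "1",
    "Lepocinclis_tripteris_MI": "1",
    "Lepocinclis_tripteris_UTEX": "1",
    "Lepocinclis_steinii": "1",
    "Lepocinclis_playfairiana": "1",
    "Lepocinclis_ovum": "1",
    "Phacus_inflexus": "0",
    "Phacus_orbicularis": "0",
    "Phacus_pleuronectes": "0",
}


def phacaceae_table() -> pd.DataFrame:
    """Printed characteristics table as a DataFrame indexed by taxon."""
    df = pd.DataFrame(list(PHACACEAE_TABLE_ROWS),
                      columns=list(PHACACEAE_TABLE_COLUMNS))
    return df.set_index("taxon")


def euglenophyta_tree():
    return read_newick(EUGLENOPHYTA_TREE_NEWICK)


def ir_character() -> BinaryCharacter:
    return BinaryCharacter(name="IR", states=dict(IR_PRESENCE))


def maturase_intron_rows() -> list[tuple[int, int]]:
    """(maturase count, intron count) for the eight new Phacaceae genomes."""
    df = phacaceae_table()
    return [(len(PHACACEAE_MATURASES[t]), int(df.loc[t, "n_introns"]))
            for t in NEW_PHACACEAE]
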