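"""Domain assignment and Fc-contact interface classification.

Nonsynonymous variants are placed into protein domains using the gene's
mature-numbered domain intervals, and classified against the receptor's
IgG-Fc contact residue set (taken from co-crystal structures of the
homologous receptor–Fc complexes and stored in the gene config).

Interface adjacency is measured in sequence positions, not 3-D distance:
a residue in the contact set is ``contact`` (distance 0), within
``window`` positions of one is ``adjacent``, anything else — including
every non-extracellular residue — is ``distal``.  A sequence-motif scan
(N-X-S/T, X ≠ P) flags variants that eliminate an N-linked glycosylation
site.
"""

from __future__ import annotations

from dataclasses import dataclass

from .gene_models import GeneModel

#: coarse labels used in the cohort variant tables
TABLE_DOMAIN = {
    "signal": "Signal",
    "extracellular-D1": "Extracellular",
    "extracellular-D2": "Extracellular",
    "extracellular-other": "Extracellular",
    "transmembrane": "Transmembrane",
    "cytoplasmic": "Cytoplasmic",
}


@dataclass(frozen=True)
class InterfaceClassification:
    mature_index: int
    domain: str
    interface_class: str       # contact | adjacent | distal
    contact_distance: int | None
    source: str


def assign_domain(mature_index: int, gene: GeneModel) -> str:
    """Fine-grained domain label for a mature residue (negative = leader)."""
    return gene.domain_label(mature_index)


def assign_table_domain(mature_index: int, gene: GeneModel) -> str:
    return TABLE_DOMAIN[assign_domain(mature_index, gene)]


def classify_interface(mature_index: int, gene: GeneModel,
                       window: int = 2) -> InterfaceClassification:
    """Classify a mature residue against the gene's Fc-contact set."""
    domain = assign_domain(mature_index, gene)
    contacts = gene.contact_residues
    if not domain.startswith("extracellular") or not contacts:
        return InterfaceClassification(mature_index, domain, "distal",
                                       None, gene.contact_source)
    dist = min(abs(mature_index - c) for c in contacts)
    if dist == 0:
        cls = "contact"
    elif dist <= window:
        cls = "adjacent"
    else:
        cls = "distal"
    return InterfaceClassification(mature_index, domain, cls, dist,
                                   gene.contact_source)


def find_glycosylation_sites(protein: str) -> list[int]:
    """1-based positions of N in N-X-S/T sequons (X ≠ P)."""
    sites = []
    for i in range(len(protein) - 2):
        if (protein[i] == "N" and protein[i + 1] != "P"
                and protein[i + 2] in "ST"):
            sites.append(i + 1)
    return sites


def destroys_glycosylation_site(gene: GeneModel, mature_index: int,
                                alt_aa: str) -> bool:
    """True when substituting ``alt_aa`` at ``mature_index`` removes a
    sequon present in the mature reference protein."""
    prot = gene.mature_protein
    if mature_index < 1 or mature_index > len(prot):
        return False
    mutant = prot[:mature_index - 1] + alt_aa + prot[mature_index:]
    before = set(find_glycosylation_sites(prot))
    after = set(find_glycosylation_sites(mutant))
    return bool(before - after)
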