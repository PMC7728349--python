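"""Static annotation of the 29 mammalian SWI/SNF (mSWI/SNF) subunits.

Each subunit of the BAF, PBAF and ncBAF chromatin remodeling complexes
is annotated with a role — ``core`` (shared scaffold/ATPase subunits),
``signature`` (complex-defining subunits) or ``accessory`` — and with
the complexes it belongs to. The table follows the modular BAF/PBAF/
ncBAF architecture: BAF155 (SMARCC1), BAF170 (SMARCC2) and BAF60A
(SMARCD1) form the shared core of all three complexes, BAF57 (SMARCE1)
and BAF47 (SMARCB1) are core subunits absent from ncBAF, ARID1A/B and
the DPF paralogs are BAF signatures, ARID2/PBRM1/BRD7/PHF10 are PBAF
signatures, and BRD9/BICRA/BICRAL are ncBAF signatures.

Lookup is by UniProt accession; unknown accessions yield None.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

__all__ = ["SubunitAnnotation", "SWISNF_SUBUNITS", "annotate_swisnf"]


@dataclass(frozen=True)
class SubunitAnnotation:
    accession: str
    gene: str
    alias: str
    role: str  # core | signature | accessory
    complexes: Tuple[str, ...]  # subset of ("BAF", "PBAF", "ncBAF")

    @property
    def in_baf(self) -> bool:
        return "BAF" in self.complexes

    @property
    def in_pbaf(self) -> bool:
        return "PBAF" in self.complexes

    @property
    def in_ncbaf(self) -> bool:
        return "ncBAF" in self.complexes


_ALL = ("BAF", "PBAF", "ncBAF")
_BP = ("BAF", "PBAF")

_TABLE = [
    # ATPase + core module
    ("P51532", "SMARCA4", "BRG1", "core", _ALL),
    ("P51531", "SMARCA2", "BRM", "core", _ALL),
    ("Q92922", "SMARCC1", "BAF155", "core", _ALL),
    ("Q8TAQ2", "SMARCC2", "BAF170", "core", _ALL),
    ("Q96GM5", "SMARCD1", "BAF60A", "core", _ALL),
    ("Q92925", "SMARCD2", "BAF60B", "core", _BP),
    ("Q6STE5", "SMARCD3", "BAF60C", "core", _BP),
    ("Q969G3", "SMARCE1", "BAF57", "core", _BP),
    ("Q12824", "SMARCB1", "BAF47", "core", _BP),
    # accessory subunits
    ("P60709", "ACTB", "beta-actin", "accessory", _ALL),
    ("O96019", "ACTL6A", "BAF53A", "accessory", _ALL),
    ("O94805", "ACTL6B", "BAF53B", "accessory", _BP),
    ("Q4VC05", "BCL7A", "BCL7A", "accessory", _ALL),
    ("Q9BQE9", "BCL7B", "BCL7B", "accessory", _ALL),
    ("Q8WUZ0", "BCL7C", "BCL7C", "accessory", _ALL),
    ("Q15532", "SS18", "SS18", "accessory", ("BAF", "ncBAF")),
    ("O75177", "SS18L1", "CREST", "accessory", ("BAF", "ncBAF")),
    # BAF signature subunits
    ("O14497", "ARID1A", "BAF250A", "signature", ("BAF",)),
    ("Q8NFD5", "ARID1B", "BAF250B", "signature", ("BAF",)),
    ("Q92782", "DPF1", "BAF45B", "signature", ("BAF",)),
    ("Q92785", "DPF2", "BAF45D", "signature", ("BAF",)),
    ("Q92784", "DPF3", "BAF45C", "signature", ("BAF",)),
    # PBAF signature subunits
    ("Q68CP9", "ARID2", "BAF200", "signature", ("PBAF",)),
    ("Q86U86", "PBRM1", "BAF180/PB1", "signature", ("PBAF",)),
    ("Q9NPI1", "BRD7", "BRD7", "signature", ("PBAF",)),
    ("Q8WUB8", "PHF10", "BAF45A/PHF10", "signature", ("PBAF",)),
    # ncBAF signature subunits
    ("Q9H8M2", "BRD9", "BRD9", "signature", ("ncBAF",)),
    ("Q9NZM4", "BICRA", "GLTSCR1", "signature", ("ncBAF",)),
    ("Q6AI39", "BICRAL", "GLTSCR1L", "signature", ("ncBAF",)),
]

SWISNF_SUBUNITS: Dict[str, SubunitAnnotation] = {
    acc: SubunitAnnotation(acc, gene, alias, role, complexes)
    for acc, gene, alias, role, complexes in _TABLE
}

assert len(SWISNF_SUBUNITS) == 29


def annotate_swisnf(accession: str) -> Optional[SubunitAnnotation]:
    """Annotation for a UniProt accession, or None if not an mSWI/SNF subunit."""
    return SWISNF_SUBUNITS.get(str(accession).strip().upper())
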