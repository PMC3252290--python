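"""Combinatorial fluorescent compound library.

The screen's library is a two-diversity combinatorial set built on a
xanthene-like (rhodamine-derived) scaffold: an R1 block (letters A..L, an
amine substituent on the tricyclic core) and an R2 block (numbers 1..33, a
substituent on the pendant phenyl ring).  A compound ID such as ``"C9"``
names its R1 letter and R2 number.  The real library's structures are not
published, so SMILES here are generated from a documented fragment table;
the one property downstream analysis relies on — compounds sharing an R1
letter share a large substructure and are therefore structurally similar —
holds by construction.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

__all__ = [
    "Compound",
    "CompoundLibrary",
    "R1_LETTERS",
    "R2_NUMBERS",
    "build_library",
    "read_smi",
    "write_smi",
]

R1_LETTERS: tuple[str, ...] = tuple(string.ascii_uppercase[:12])  # A..L
R2_NUMBERS: tuple[int, ...] = tuple(range(1, 34))  # 1..33

# 9-aryl xanthene core with a fixed dimethylamino auxochrome; {r1} is the
# variable amine on the opposite ring, {r2} decorates the pendant phenyl.
SCAFFOLD_TEMPLATE = "O1c2cc({r1})ccc2C(c2ccccc2{r2})c2ccc(N(C)C)cc21"

# R1 fragments: large, chemically diverse amines so the R1 block dominates
# path-fingerprint similarity.  Fragment rings use closure digit 3 only:
# the scaffold's digits 1 and 2 are still open at the insertion point, and
# reusing them would silently close the wrong ring.
R1_FRAGMENTS: dict[str, str] = {
    "A": "N(CCCC)CCCC",
    "B": "N3CCCCC3CC(C)C",
    "C": "N3CCOCC3C(=O)NCCF",
    "D": "NC(=O)C(C)(C)CC(=O)OC",
    "E": "N(CC#C)Cc3cc(F)cc(F)c3",
    "F": "N3CCN(CCCO)CC3",
    "G": "NCc3ccc(-c4ccco4)o3",
    "H": "NCc3ccc(S(=O)(=O)C)s3",
    "I": "N(CCO)CCOCCOC",
    "J": "NC3CCC(C(F)(F)F)CC3",
    "K": "NCc3ccc(OCc4ccccc4)cc3",
    "L": "N(C)Cc3ccnc(N(C)C)c3",
}

# R2 fragments: small substituents — halogens, short chains, polar heads.
R2_FRAGMENTS: dict[int, str] = {
    1: "F", 2: "Cl", 3: "Br", 4: "C", 5: "CC", 6: "CCC", 7: "C(C)C",
    8: "O", 9: "OC", 10: "OCC", 11: "C#N", 12: "C(F)(F)F", 13: "C=C",
    14: "CO", 15: "N", 16: "NC", 17: "N(C)C", 18: "C(=O)O", 19: "C(=O)OC",
    20: "C(=O)N", 21: "S", 22: "SC", 23: "C(=O)C", 24: "OC(C)C", 25: "CCO",
    26: "OCC=C", 27: "CC#N", 28: "C(C)(C)C", 29: "OC(F)F", 30: "CCl",
    31: "CF", 32: "CBr", 33: "CCCC",
}

MAX_LIBRARY_SIZE = len(R1_LETTERS) * len(R2_NUMBERS)  # 396


@dataclass(frozen=True)
class Compound:
    compound_id: str
    r1: str
    r2: int
    smiles: str


@dataclass
class CompoundLibrary:
    """Ordered collection of library compounds with R1/R2 block structure."""

    compounds: list[Compound] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.compounds)

    def __iter__(self):
        return iter(self.compounds)

    @property
    def ids(self) -> list[str]:
        return [c.compound_id for c in self.compounds]

    def get(self, compound_id: str) -> Compound:
        for c in self.compounds:
            if c.compound_id == compound_id:
                return c
        raise KeyError(f"compound {compound_id!r} not in library")

    def r1_blocks(self) -> dict[str, list[Compound]]:
        blocks: dict[str, list[Compound]] = {}
        for c in self.compounds:
            blocks.setdefault(c.r1, []).append(c)
        return blocks


def _make_smiles(r1: str, r2: int) -> str:
    return SCAFFOLD_TEMPLATE.format(r1=R1_FRAGMENTS[r1], r2=R2_FRAGMENTS[r2])


def build_library(
    seed: int = 0,
    n_compounds: int = 240,
    membership_rule: str = "first_20_r2_per_r1",
) -> CompoundLibrary:
    """Construct the synthetic combinatorial library.

    Parameters
    ----------
    seed
        Accepted for interface uniformity; membership rules here are
        deterministic, so the seed does not alter the output.
    n_compounds
        Library size; at most 396 (the full 12 x 33 grid).
    membership_rule
        ``"first_20_r2_per_r1"`` — the default 240-compound design, the
        first 20 R2 numbers for each of the 12 R1 letters;
        ``"all"`` — every (R1, R2) pair, truncated to ``n_compounds`` in
        row-major (R1-major) order.

    Returns
    -------
    CompoundLibrary
        Deterministic given the arguments; compound IDs unique.
    """
    if n_compounds > MAX_LIBRARY_SIZE:
        raise ValueError(
            f"n_compounds={n_compounds} exceeds the {MAX_LIBRARY_SIZE}-member "
            "R1 x R2 grid"
        )
    if membership_rule == "first_20_r2_per_r1":
        per_block = -(-n_compounds // len(R1_LETTERS))  # ceil
        grid = [
            (r1, r2)
            for r1 in R1_LETTERS
            for r2 in R2_NUMBERS[:per_block]
        ][:n_compounds]
    elif membership_rule == "all":
        grid = [(r1, r2) for r1 in R1_LETTERS for r2 in R2_NUMBERS][:n_compounds]
    else:
        raise ValueError(f"unknown membership_rule {membership_rule!r}")

    compounds = [
        Compound(f"{r1}{r2}", r1, r2, _make_smiles(r1, r2)) for r1, r2 in grid
    ]
    return CompoundLibrary(compounds)


def write_smi(library: CompoundLibrary, path) -> None:
    """Write a standard .smi file: SMILES, tab, compound ID per line."""
    with open(path, "w") as fh:
        for c in library:
            fh.write(f"{c.smiles}\t{c.compound_id}\n")


def read_smi(path) -> CompoundLibrary:
    compounds = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            smiles, cid = line.split("\t")
            r1, r2 = cid[0], int(cid[1:])
            compounds.append(Compound(cid, r1, r2, smiles))
    return CompoundLibrary(compounds)
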