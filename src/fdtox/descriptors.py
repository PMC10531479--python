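"""Structure-derived descriptors for the binding-score QSAR models.

Three descriptor sets feed the models:

* ``TD`` — topological diameter, the longest shortest-path (in bonds) on the
  hydrogen-depleted graph; the molecular-size descriptor.
* ``QPpolrz`` — polarizability volume in cubic angstroms. When the input
  table ships a QPpolrz column it is used verbatim; otherwise an additive
  atomic-increment proxy is computed (see :func:`polarizability_proxy`).
* 25 drug-like descriptors (H-bonding counts, surface areas, logP/logS,
  ring/atom counts, functional-group counts).

The drug-like set follows documented RDKit-based conventions (table below);
bit-exact parity with any particular desktop package is a non-goal.

==================== =====================================================
slot                 convention
==================== =====================================================
h_acceptors          Lipinski N+O count
h_donors             Lipinski NH+OH count
tsa                  Labute approximate surface area (Å²)
psa                  topological polar surface area (Ertl fragment TPSA)
rpsa                 psa / tsa, clipped to [0, 1]
drug_likeness        QED (quantitative estimate of drug-likeness), [0, 1]
mw                   average molecular weight (g/mol)
clogp                Wildman–Crippen atom-contribution logP
clogs                Delaney ESOL estimated log10 aqueous solubility
electronegative_atoms atoms more electronegative than carbon: N,O,F,Cl,Br,I
stereo_centers       tetrahedral stereocenters incl. unassigned
rotatable_bonds      non-ring single bonds between non-terminal heavy atoms
ring_closures        cyclomatic number of the heavy-atom graph
small_rings          SSSR rings of size <= 7
aromatic_rings       SSSR rings with all atoms aromatic
aromatic_atoms       atoms flagged aromatic
sp3_atoms            heavy atoms with sp3 hybridization
symmetric_atoms      atoms in a graph-symmetry class of size >= 2
amides               C(=O)N matches
amines               trivalent non-amide, non-aromatic-ring N
aromatic_nitrogen    aromatic N atoms
basic_nitrogen       aliphatic amine N (not anilinic/amide) or N+
acidic_oxygen        acidic OH oxygens on C(=O), P(=O) or S(=O)(=O)
non_h_atoms          heavy-atom count
non_ch_atoms         heavy atoms that are not carbon
==================== =====================================================
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, QED, rdMolDescriptors

from .errors import DescriptorError, DomainError, ParseError

DRUG_LIKE_COLUMNS = [
    "h_acceptors", "h_donors", "tsa", "rpsa", "psa", "drug_likeness", "mw",
    "clogp", "clogs", "electronegative_atoms", "stereo_centers",
    "rotatable_bonds", "ring_closures", "small_rings", "aromatic_rings",
    "aromatic_atoms", "sp3_atoms", "symmetric_atoms", "amides", "amines",
    "aromatic_nitrogen", "basic_nitrogen", "acidic_oxygen", "non_h_atoms",
    "non_ch_atoms",
]

#: full predictor block before the optimal descriptor (DCW) is attached
DESCRIPTOR_COLUMNS = ["QPpolrz", "TD"] + DRUG_LIKE_COLUMNS

_INT_COLUMNS = {
    "h_acceptors", "h_donors", "electronegative_atoms", "stereo_centers",
    "rotatable_bonds", "ring_closures", "small_rings", "aromatic_rings",
    "aromatic_atoms", "sp3_atoms", "symmetric_atoms", "amides", "amines",
    "aromatic_nitrogen", "basic_nitrogen", "acidic_oxygen", "non_h_atoms",
    "non_ch_atoms",
}

# Additive atomic polarizability increments (A^3), adapted from Miller's
# atomic hybrid components for the dipole polarizability. Hybridization-aware
# for carbon and nitrogen; element-level elsewhere.
POLARIZABILITY_INCREMENTS: dict[str, float] = {
    "H": 0.387,
    "C.sp3": 1.061,
    "C.sp2": 1.352,
    "C.sp": 1.283,
    "N.sp3": 0.964,
    "N.sp2": 1.030,
    "O": 0.637,
    "F": 0.296,
    "Cl": 2.315,
    "Br": 3.013,
    "I": 5.415,
    "S": 2.980,
    "P": 1.538,
}

_AMIDE = Chem.MolFromSmarts("[CX3](=[OX1])[NX3]")
_AMINE = Chem.MolFromSmarts("[NX3;!$([NX3]C=O);!$([NX3]=*);!$([NX3]~[OX1]);!a]")
_BASIC_N = Chem.MolFromSmarts(
    "[$([NX3;!$(NC=O);!$(N[a]);!$(N~[OX1]);!a]),$([NX4+;!$(N=O)])]"
)
_ACIDIC_O = Chem.MolFromSmarts(
    "[OX2H1][$([CX3]=O),$([PX4]=O),$([SX4](=O)=O)]"
)
_ELECTRONEG = frozenset([7, 8, 9, 17, 35, 53])


def parse_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string, keeping the largest fragment of a salt.

    Raises :class:`ParseError` with the offending SMILES echoed.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise ParseError(f"empty or non-string SMILES: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    return mol


def topological_diameter(mol: Chem.Mol) -> int:
    """Longest shortest path, in bonds, over the hydrogen-depleted graph.

    Computed on the largest connected component; a single heavy atom has
    diameter 0. Empty molecules are outside the domain.
    """
    mol = Chem.RemoveHs(mol)
    if mol.GetNumHeavyAtoms() == 0:
        raise DomainError("topological diameter undefined for an empty molecule")
    frag_ids = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    frag = max(frag_ids, key=lambda m: m.GetNumHeavyAtoms())
    if frag.GetNumAtoms() == 1:
        return 0
    dm = Chem.GetDistanceMatrix(frag)
    return int(dm[np.isfinite(dm)].max())


def polarizability_proxy(mol: Chem.Mol) -> float:
    """Additive polarizability-volume estimate (Å³).

    Sums per-atom increments (hydrogens included via implicit counts), so it
    is strictly additive over disconnected fragments. Used only when a
    supplied QPpolrz column is absent; the provenance flag records which.
    """
    if mol.GetNumAtoms() == 0:
        raise DomainError("polarizability undefined for an empty molecule")
    total = 0.0
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym == "C":
            hyb = atom.GetHybridization()
            key = {
                Chem.HybridizationType.SP3: "C.sp3",
                Chem.HybridizationType.SP2: "C.sp2",
                Chem.HybridizationType.SP: "C.sp",
            }.get(hyb, "C.sp3")
        elif sym == "N":
            key = "N.sp3" if atom.GetHybridization() == Chem.HybridizationType.SP3 else "N.sp2"
        else:
            key = sym
        if key not in POLARIZABILITY_INCREMENTS:
            raise DescriptorError(
                f"element {sym!r} missing from the polarizability increment table"
            )
        total += POLARIZABILITY_INCREMENTS[key]
        total += atom.GetTotalNumHs() * POLARIZABILITY_INCREMENTS["H"]
    return total


def _symmetric_atoms(mol: Chem.Mol) -> int:
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=False))
    counts: dict[int, int] = {}
    for r in ranks:
        counts[r] = counts.get(r, 0) + 1
    return sum(c for c in counts.values() if c >= 2)


def compute_drug_like(mol: Chem.Mol) -> dict[str, float]:
    """The 25 drug-like descriptors under the conventions in the module table."""
    if mol.GetNumHeavyAtoms() == 0:
        raise DomainError("drug-like descriptors undefined for an empty molecule")
    heavy = mol.GetNumHeavyAtoms()
    tsa = rdMolDescriptors.CalcLabuteASA(mol)
    psa = rdMolDescriptors.CalcTPSA(mol)
    clogp = Crippen.MolLogP(mol)
    mw = Descriptors.MolWt(mol)
    rotb = rdMolDescriptors.CalcNumRotatableBonds(mol)
    arom_atoms = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())
    # Delaney ESOL: log10(S) from logP, MW, rotatable bonds, aromatic proportion
    clogs = 0.16 - 0.63 * clogp - 0.0062 * mw + 0.066 * rotb - 0.74 * (arom_atoms / heavy)
    ring_info = mol.GetRingInfo()
    n_frags = len(Chem.GetMolFrags(mol))
    try:
        qed = QED.qed(mol)
    except Exception:  # QED is undefined for some exotic valence states
        qed = 0.0
    vals: dict[str, float] = {
        "h_acceptors": Lipinski.NOCount(mol),
        "h_donors": Lipinski.NHOHCount(mol),
        "tsa": tsa,
        "psa": psa,
        "rpsa": min(1.0, psa / tsa) if tsa > 0 else 0.0,
        "drug_likeness": qed,
        "mw": mw,
        "clogp": clogp,
        "clogs": clogs,
        "electronegative_atoms": sum(
            1 for a in mol.GetAtoms() if a.GetAtomicNum() in _ELECTRONEG
        ),
        "stereo_centers": len(
            Chem.FindMolChiralCenters(mol, includeUnassigned=True, useLegacyImplementation=False)
        ),
        "rotatable_bonds": rotb,
        "ring_closures": mol.GetNumBonds() - heavy + n_frags,
        "small_rings": sum(1 for r in ring_info.AtomRings() if len(r) <= 7),
        "aromatic_rings": rdMolDescriptors.CalcNumAromaticRings(mol),
        "aromatic_atoms": arom_atoms,
        "sp3_atoms": sum(
            1 for a in mol.GetAtoms()
            if a.GetHybridization() == Chem.HybridizationType.SP3
        ),
        "symmetric_atoms": _symmetric_atoms(mol),
        "amides": len(mol.GetSubstructMatches(_AMIDE, uniquify=True)),
        "amines": len(mol.GetSubstructMatches(_AMINE, uniquify=True)),
        "aromatic_nitrogen": sum(
            1 for a in mol.GetAtoms() if a.GetIsAromatic() and a.GetAtomicNum() == 7
        ),
        "basic_nitrogen": len(mol.GetSubstructMatches(_BASIC_N, uniquify=True)),
        "acidic_oxygen": len(mol.GetSubstructMatches(_ACIDIC_O, uniquify=True)),
        "non_h_atoms": heavy,
        "non_ch_atoms": sum(
            1 for a in mol.GetAtoms() if a.GetAtomicNum() not in (1, 6)
        ),
    }
    for col in _INT_COLUMNS:
        vals[col] = int(vals[col])
    return vals


def compute_descriptor_table(
    smiles: "pd.Series | list[str]",
    supplied: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Descriptor table (27 columns) for a batch of SMILES.

    ``supplied`` may carry precomputed columns (e.g. QPpolrz from an external
    source); supplied values take precedence column-wise and the returned
    provenance map records ``"supplied"`` vs ``"computed"`` per column.
    """
    smiles = pd.Series(smiles)
    rows = []
    for smi in smiles:
        mol = parse_smiles(smi)
        row = {"QPpolrz": polarizability_proxy(mol), "TD": topological_diameter(mol)}
        row.update(compute_drug_like(mol))
        rows.append(row)
    table = pd.DataFrame(rows, index=smiles.index)[DESCRIPTOR_COLUMNS]
    provenance = {col: "computed" for col in DESCRIPTOR_COLUMNS}
    if supplied is not None:
        for col in supplied.columns:
            if col in table.columns:
                table[col] = np.asarray(supplied[col], dtype=float)
                provenance[col] = "supplied"
    return table, provenance


def write_descriptor_table(table: pd.DataFrame, provenance: dict[str, str],
                           csv_path, sidecar_path=None) -> None:
    """CSV output with a JSON provenance sidecar."""
    table.to_csv(csv_path, index=True, index_label="id")
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)
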