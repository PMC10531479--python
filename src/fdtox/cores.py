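"""Fullerene cores used by the structure generator.

Two cores are available:

``"proxy"``
    Corannulene (C20H10), the smallest curved fullerene fragment
    ("buckybowl"). Ten rim CH positions give cheap, unambiguous attachment
    sites, and parsing/drawing is fast. This is the default: downstream
    code must not depend on core size.

``"c60"``
    A literal Kekulé SMILES of buckminsterfullerene. The string was derived
    from the truncated-icosahedron graph with the canonical Kekulé structure
    that places all 30 double bonds on hexagon–hexagon edges; it round-trips
    through RDKit as C60. C60 carries no hydrogens, so substitution there
    converts a double bond to a single bond and saturates the partner carbon
    — the same 1,2-addition motif real fullerene chemistry uses.
"""

from rdkit import Chem

from .errors import ConfigurationError

CORANNULENE = "c1cc2ccc3ccc4ccc5ccc1c1c2c3c4c51"

C60 = (
    "c12c3c4c5c1c1c6c7c2c2c8c3c3c9c4c4c%10c5c5c1c1c6c6c%11c7c2c2c7c8c3c3c8"
    "c9c4c4c9c%10c5c5c1c1c6c6c%11c2c2c7c3c3c8c4c4c9c5c1c1c6c2c3c41"
)

_CORES = {"proxy": CORANNULENE, "c60": C60}


def core_smiles(spec: str) -> str:
    """Resolve a core spec to a SMILES string.

    ``spec`` may be one of the registered names (``"proxy"``, ``"c60"``) or a
    literal SMILES, which must parse.
    """
    if spec in _CORES:
        return _CORES[spec]
    mol = Chem.MolFromSmiles(spec)
    if mol is None:
        raise ConfigurationError(
            f"core_spec {spec!r} is neither a registered core name "
            f"({sorted(_CORES)}) nor a valid SMILES"
        )
    return spec
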