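"""Shared construction helpers for tests."""
import numpy as np

from isopeptide_detect.structure_io import Structure
from isopeptide_detect.synthetic import (
    TOPOLOGY_ANGLES,
    _dress_chain,
    _make_residue,
    _self_avoiding_walk,
    build_triad_atoms,
)
from isopeptide_detect.templates import TRIAD_TYPES


def designed_plant(
    letters: str,
    lys_idx: int,
    cat_idx: int,
    acc_idx: int,
    triad_type: str = "Lys-Asn-Asp",
    topology: str = "CnaA-like",
    seed: int = 0,
    structure_id: str = "designed",
) -> Structure:
    """A planted-bond structure whose chain sequence is fully specified.

    ``letters`` is the one-letter sequence of the whole chain; the letters at
    the triad indices are overridden by the triad residue types.  Used when a
    test needs exact control of the flank sequence.
    """
    rng = np.random.default_rng(seed)
    centers = TOPOLOGY_ANGLES[topology]
    triad = build_triad_atoms(
        triad_type, 1.33, (centers["phi"], centers["psi"], centers["omega"])
    )
    lys_name, acc_name, cat_name = TRIAD_TYPES[triad_type]
    triad_coords = np.vstack([np.array(list(d.values())) for d in triad.values()])
    n = len(letters)
    flank_idx = [i for i in range(n) if i not in (lys_idx, cat_idx, acc_idx)]
    trace = _self_avoiding_walk(
        len(flank_idx), rng, triad_coords.mean(axis=0) + np.array([30.0, 0.0, 0.0]),
        forbidden=triad_coords, forbidden_sep=16.0,
    )
    flank_letters = "".join(letters[i] for i in flank_idx)
    residues = _dress_chain(
        trace, flank_letters, "A", [i + 1 for i in flank_idx], rng, side_chains=False
    )
    by_id = {r.seq_id: r for r in residues}
    by_id[lys_idx + 1] = _make_residue("A", lys_idx + 1, lys_name, triad["bond_lys"])
    by_id[cat_idx + 1] = _make_residue("A", cat_idx + 1, cat_name, triad["catalytic"])
    by_id[acc_idx + 1] = _make_residue("A", acc_idx + 1, acc_name, triad["bond_acceptor"])
    chain = [by_id[i] for i in sorted(by_id)]
    return Structure(id=structure_id, chains={"A": chain})


# conservative-substitution scheme used to engineer exact flank identities:
# every partner scores positively in BLOSUM62, so the ungapped alignment
# stays optimal while exact matches drop
SIMILAR = {
    "A": "S", "D": "E", "E": "D", "F": "Y", "H": "N", "I": "V", "K": "R",
    "L": "M", "M": "L", "N": "H", "Q": "E", "R": "K", "S": "T", "T": "S",
    "V": "I", "W": "Y", "Y": "F",
}
ENGINEER_POOL = "ADEFHIKLMNQRSTVWY"


def mutate_to_identity(seq: str, n_keep: int) -> str:
    """Conservatively mutate all but ``n_keep`` evenly spread positions."""
    idx = set(
        np.linspace(0, len(seq) - 1, n_keep).round().astype(int).tolist()
    ) if n_keep else set()
    return "".join(c if i in idx else SIMILAR[c] for i, c in enumerate(seq))
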