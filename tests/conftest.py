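import gemmi
import numpy as np
import pytest


@pytest.fixture
def build_structure():
    """Factory for small in-memory gemmi structures from atom tuples.

    Atoms are (chain, res_name, res_seq, atom_name, element, (x, y, z))
    and optionally a trailing occupancy / altloc.
    """

    def _build(atoms):
        st = gemmi.Structure()
        st.name = "fixture"
        model = gemmi.Model("1")
        chains: dict[str, gemmi.Chain] = {}
        residues: dict[tuple, gemmi.Residue] = {}
        for entry in atoms:
            chain_name, res_name, res_seq, atom_name, element, xyz = entry[:6]
            occ = entry[6] if len(entry) > 6 else 1.0
            altloc = entry[7] if len(entry) > 7 else "\0"
            if chain_name not in chains:
                chains[chain_name] = gemmi.Chain(chain_name)
            key = (chain_name, res_seq, res_name)
            if key not in residues:
                res = gemmi.Residue()
                res.name = res_name
                res.seqid = gemmi.SeqId(res_seq, " ")
                residues[key] = res
            atom = gemmi.Atom()
            atom.name = atom_name
            atom.element = gemmi.Element(element)
            atom.pos = gemmi.Position(*map(float, xyz))
            atom.occ = occ
            atom.altloc = altloc
            residues[key].add_atom(atom)
        for (chain_name, _, _), res in residues.items():
            chains[chain_name].add_residue(res)
        for chain in chains.values():
            model.add_chain(chain)
        st.add_model(model)
        st.setup_entities()
        return st

    return _build


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
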