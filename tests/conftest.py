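import numpy as np
import pytest

from tcrcurate.numbering import NumberedChain, load_profiles
from tcrcurate.structure_io import Atom, Chain, Residue
from tcrcurate.synthetic import FixtureSpec, make_tcr_mhc_fixture


def make_point_chain(chain_id, chain_type, imgt_to_ca, species="human",
                     cb_offset=(0.0, 0.0, 1.5)):
    """A minimal numbered chain with one residue per requested IMGT position.

    ``imgt_to_ca`` maps an integer IMGT position (or (pos, icode)) to a CA
    coordinate; each residue also carries a CB at a fixed offset.  The chain
    type is injected through a dummy domain hit so the pairing stage treats
    the chain accordingly.
    """
    residues = []
    imgt_map = {}
    for i, (imgt, ca) in enumerate(sorted(
            ((k, "") if isinstance(k, int) else k, v)
            for k, v in imgt_to_ca.items())):
        ca = np.asarray(ca, float)
        atoms = [
            Atom("N", "N", ca + (-1.2, 0.4, 0.0)),
            Atom("CA", "C", ca),
            Atom("C", "C", ca + (1.2, 0.4, 0.0)),
            Atom("O", "O", ca + (1.4, 1.6, 0.0)),
            Atom("CB", "C", ca + np.asarray(cb_offset)),
        ]
        res = Residue(chain_id=chain_id, seq_pos=i + 1, icode="",
                      res_name="ALA", atoms=atoms)
        residues.append(res)
        imgt_map[res.key] = imgt
    chain = Chain(chain_id=chain_id, residues=residues)
    numbered = NumberedChain(chain=chain, hits=[], imgt_map=imgt_map)

    class _Hit:
        pass

    hit = _Hit()
    hit.chain_type = chain_type
    hit.species = species
    numbered.hits = [hit]
    return numbered


@pytest.fixture(scope="session")
def profiles():
    return load_profiles()


@pytest.fixture(scope="session")
def default_fixture():
    """One standard αβ/MH1/peptide fixture shared by read-only tests."""
    return make_tcr_mhc_fixture(FixtureSpec())


@pytest.fixture()
def point_chain_factory():
    return make_point_chain
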