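import numpy as np
import pytest

from poseval.structio import Atom, MolecularStructure


def make_atom(serial, element, xyz, name=None, res_name="UNK", res_id=1,
              chain="A", **params):
    defaults = dict(charge=0.0, lj_sigma=3.4, lj_epsilon=0.1,
                    gb_radius=1.7, gb_screen=0.8)
    defaults.update(params)
    return Atom(serial, name or element, element, res_name, res_id, chain,
                np.asarray(xyz, dtype=float), **defaults)


def make_structure(specs, roles=None, **params):
    """Quick structure from (element, xyz) or (element, xyz, dict) tuples."""
    atoms = []
    for i, spec in enumerate(specs):
        el, xyz = spec[0], spec[1]
        extra = dict(params)
        if len(spec) > 2:
            extra.update(spec[2])
        atoms.append(make_atom(i + 1, el, xyz, **extra))
    return MolecularStructure(atoms, roles or ["other"] * len(atoms))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
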