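"""Shared fixtures: toy structures, plans, and record factories."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from spies3d.fragmentation import Fragment, FragmentationPlan, build_fragmentation
from spies3d.spies_core import SPIERecord
from spies3d.structure_model import Atom, Residue, Structure
from spies3d.synthetic_fixtures import ToyComplexSpec, make_toy_complex

_counter = itertools.count(1)


@pytest.fixture
def ala3():
    """Zwitterionic Ala-Ala-Ala single chain (no waters)."""
    return make_toy_complex(
        ToyComplexSpec(n_chains=1, residues_per_chain=3, n_waters=0)
    )


@pytest.fixture
def toy_complex():
    """Two poly-Ala chains at a 4.5 Å gap with two interface waters."""
    return make_toy_complex(ToyComplexSpec())


@pytest.fixture
def toy_plan(toy_complex):
    return build_fragmentation(toy_complex)


def make_record(
    label_i,
    label_j,
    chain_i="A",
    chain_j="B",
    kind_i="residue",
    kind_j="residue",
    resseq_i=1,
    resseq_j=2,
    distance=4.0,
    pie=-5.0,
    iclass=None,
    group_i=None,
    group_j=None,
):
    i = next(_counter)
    return SPIERecord(
        frag_i=i,
        frag_j=i + 1,
        label_i=label_i,
        label_j=label_j,
        chain_i=chain_i,
        chain_j=chain_j,
        kind_i=kind_i,
        kind_j=kind_j,
        resseq_i=resseq_i,
        resseq_j=resseq_j,
        distance=distance,
        pie=pie,
        components={
            "e_es": pie,
            "e_ex": 0.0,
            "e_ct_mix": 0.0,
            "e_di": 0.0,
            "g_sol": 0.0,
        },
        iclass=iclass,
        group_i=group_i,
        group_j=group_j,
    )


def point_cloud_plan(rng, n_frags, max_atoms=4, spread=10.0):
    """A FragmentationPlan + Structure of random water point clouds.

    Used to cross-check distance code against brute force without any
    peptide bookkeeping in the way.
    """
    residues = []
    fragments = []
    serial = itertools.count(1)
    for i in range(1, n_frags + 1):
        n_atoms = int(rng.integers(1, max_atoms + 1))
        center = rng.uniform(-spread, spread, 3)
        atoms = tuple(
            Atom(
                serial=next(serial),
                name=f"O{k}" if k else "O",
                element="O",
                coords=tuple(np.round(center + rng.uniform(-1.5, 1.5, 3), 3)),
            )
            for k in range(n_atoms)
        )
        res = Residue(
            chain_id="W", resseq=i, icode="", resname="HOH", atoms=atoms,
            kind="water", het=True,
        )
        residues.append(res)
        fragments.append(
            Fragment(
                index=i,
                label=f"HOH{i}:W",
                member_atoms=frozenset(
                    ("W", i, "", a.name) for a in atoms
                ),
                charge=0,
                kind="water",
                source_residues=(("W", i, ""),),
            )
        )
    structure = Structure(residues=tuple(residues), chain_order=("W",))
    plan = FragmentationPlan(
        fragments=tuple(fragments), detached_bonds=(), total_charge=0
    )
    return plan, structure
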