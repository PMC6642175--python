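import math

import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from edgotype.structures import ChainStructure


def brute_force_interface(
    chain_a: ChainStructure, chain_b: ChainStructure, cutoff: float
) -> tuple[set[int], set[int]]:
    """O(n^2) all-pairs atom-distance oracle, plain Python loops."""
    iface_a: set[int] = set()
    iface_b: set[int] = set()
    for ra in chain_a.residues:
        for rb in chain_b.residues:
            best = math.inf
            for a in ra.atoms:
                for b in rb.atoms:
                    d = math.sqrt(
                        (a.x - b.x) ** 2 + (a.y - b.y) ** 2 + (a.z - b.z) ** 2
                    )
                    if d < best:
                        best = d
            if best <= cutoff:
                iface_a.add(ra.seqres_position)
                iface_b.add(rb.seqres_position)
    return iface_a, iface_b


@pytest.fixture(scope="session")
def small_world():
    """A small but complete synthetic world shared across tests."""
    from edgotype.synthetic import SyntheticWorldConfig, generate_world

    cfg = SyntheticWorldConfig(
        n_proteins=30,
        n_ppis=20,
        mean_protein_length=60,
        interface_width=4,
        n_disease_mut=40,
        n_nondisease_mut=60,
        true_pEgivenM=0.4,
        true_pEgivenN=0.15,
        seed=11,
    )
    return generate_world(cfg)
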