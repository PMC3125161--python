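import numpy as np
import pytest

from flexalign.synthetic import DomainSpec, make_domain


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def helix20():
    return make_domain(DomainSpec((("helix", 20),), seed=1))


@pytest.fixture
def mixed_domain():
    """~60-residue helix/loop/strand domain used across modules."""
    return make_domain(
        DomainSpec(
            (("helix", 16), ("loop", 4), ("strand", 8), ("loop", 4),
             ("helix", 14), ("loop", 4), ("strand", 8)),
            seed=11,
        )
    )


def write_ca_pdb(path, coords, chain="A", altloc_extra=None):
    """Minimal hand-built Cα-only PDB writer for parser tests.

    ``altloc_extra`` = (site_index, altloc_char, coords) inserts a duplicate
    Cα record for one residue after its primary record.
    """
    lines = []
    serial = 1
    for i, (x, y, z) in enumerate(coords):
        lines.append(
            f"ATOM  {serial:5d}  CA AALA {chain}{i + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C  "
        )
        serial += 1
        if altloc_extra is not None and altloc_extra[0] == i:
            _, alt, (ax, ay, az) = altloc_extra
            lines.append(
                f"ATOM  {serial:5d}  CA {alt}ALA {chain}{i + 1:4d}    "
                f"{ax:8.3f}{ay:8.3f}{az:8.3f}  1.00  0.00           C  "
            )
            serial += 1
    lines += ["TER", "END"]
    path.write_text("\n".join(lines) + "\n")
    return path
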