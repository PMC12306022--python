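import numpy as np
import pytest

from isomotif import fixtures as fx


@pytest.fixture(scope="session")
def duplex8():
    """16-residue ideal A-form duplex."""
    return fx.build_duplex(fx.HelixSpec("GGAUCCAU"))


@pytest.fixture(scope="session")
def kink_toy():
    """14-residue kinked module + positive (60 nt) and decoy (30 nt) queries."""
    return fx.build_kink_toy()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_rotation(rng) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


# PDB fixed-column ATOM/HETATM line writer for hand-made parser fixtures
def pdb_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resnum: int,
    xyz,
    *,
    record: str = "ATOM",
    altloc: str = " ",
    icode: str = " ",
    occupancy: float = 1.0,
    element: str | None = None,
) -> str:
    x, y, z = xyz
    el = element if element is not None else name.strip()[0]
    padded_name = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record:<6s}{serial:>5d} {padded_name:<4s}{altloc}{resname:>3s} {chain}"
        f"{resnum:>4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{0.0:6.2f}"
        f"          {el:>2s}"
    )


def make_pdb(lines: list[str]) -> str:
    return "\n".join(lines + ["END"]) + "\n"


def simple_residue_lines(
    resname: str,
    chain: str,
    resnum: int,
    origin,
    *,
    start_serial: int = 1,
    purine: bool | None = None,
    icode: str = " ",
    skip: set | None = None,
) -> list[str]:
    """ATOM lines of one minimal nucleotide shifted to ``origin``."""
    if purine is None:
        purine = resname.strip() in ("A", "G", "DA", "DG")
    gly, third = ("N9", "C6") if purine else ("N1", "C4")
    template = [
        ("P", (0.0, 0.0, -2.0)),
        ("O5'", (0.4, 0.3, -1.2)),
        ("C1'", (1.0, 0.2, 0.0)),
        (gly, (2.2, 0.5, 0.3)),
        ("C2", (3.4, 1.4, 0.2)),
        (third, (3.1, -0.9, 0.8)),
        ("O3'", (1.8, 1.2, 1.4)),
    ]
    ox, oy, oz = origin
    lines = []
    serial = start_serial
    for name, (dx, dy, dz) in template:
        if skip and name in skip:
            continue
        lines.append(
            pdb_atom_line(serial, name, resname, chain, resnum,
                          (ox + dx, oy + dy, oz + dz), icode=icode)
        )
        serial += 1
    return lines
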