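"""Synthetic fixtures for the substrate-prediction pipeline.

Two generators:

* :func:`generate_proteome` — a motif-planted proteome: proteins carrying
  annotated phosphotyrosine sites whose flanks are drawn either from a
  position-specific motif (the "planted" positive class, by default acidic
  N-terminal to the pY, echoing known PTP1B substrate peptides such as
  EEEDIpYEVLPD) or from the background distribution ("background" decoys),
  plus unannotated proteins that supply background tyrosine windows.  A
  truth table labels every annotated site.

* :func:`generate_toy_pose` — an idealised phosphatase fragment (Arg-47,
  Asp-48 and a P-loop of glycines at residues 214-221) plus a 5-residue
  phosphopeptide, constructed so that each pose-acceptance criterion can be
  switched on or off independently with at least 0.5 A of geometric margin.
  The scaffold is deliberately unphysical: only the criteria geometry
  matters.

Everything is deterministic given the seed in the spec / the ``seed``
argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence_library import AA20, FLANK, PeptideWindow, PhosphoSite, ProteinRecord

__all__ = [
    "MotifSpec",
    "SyntheticProteome",
    "DEFAULT_MOTIF",
    "HUMAN_AA_FREQS",
    "generate_proteome",
    "sample_windows",
    "generate_toy_pose",
    "write_proteome",
]

#: default planted motif: acidic stretch N-terminal to the pY with a
#: hydrophobic -1 and E/V/L/P-like C-terminal flank (cf. EEEDIpYEVLPD).
DEFAULT_MOTIF: dict[int, tuple[str, float]] = {
    -5: ("DE", 0.75),
    -4: ("DE", 0.75),
    -3: ("DE", 0.75),
    -2: ("DE", 0.75),
    -1: ("ILV", 0.75),
    1: ("DE", 0.75),
    2: ("VAI", 0.75),
    3: ("LIV", 0.75),
    4: ("PG", 0.75),
    5: ("DE", 0.75),
}

#: human-proteome-like amino-acid frequencies (UniProt/SwissProt order of
#: magnitude, rounded); provided as a preset so nothing is downloaded.
HUMAN_AA_FREQS: dict[str, float] = {
    "A": 0.070, "C": 0.023, "D": 0.047, "E": 0.071, "F": 0.037,
    "G": 0.066, "H": 0.026, "I": 0.043, "K": 0.057, "L": 0.100,
    "M": 0.021, "N": 0.036, "P": 0.063, "Q": 0.048, "R": 0.056,
    "S": 0.083, "T": 0.054, "V": 0.060, "W": 0.012, "Y": 0.027,
}


@dataclass(frozen=True)
class MotifSpec:
    """Parameters of the synthetic proteome.

    ``motif`` maps flanking position (-5..-1, 1..5) to ``(preferred_residues,
    weight)``: with probability ``weight`` the residue is drawn uniformly
    from the preferred set, otherwise from ``background``.  Setting all
    weights to 0 makes planted sites statistically identical to background.
    """

    motif: dict[int, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_MOTIF)
    )
    background: dict[str, float] | None = None  # None = uniform over 20 AA
    n_positive_sites: int = 50
    n_decoy_sites: int = 450
    n_background_proteins: int = 150
    protein_length: tuple[int, int] = (60, 120)
    seed: int = 0

    def __post_init__(self) -> None:
        for pos, (residues, weight) in self.motif.items():
            if pos == 0 or not -5 <= pos <= 5:
                raise ValueError(f"motif position {pos} outside -5..5 (0 excluded)")
            if weight < 0:
                raise ValueError(f"motif weight at {pos} is negative")
            if weight > 0 and not residues:
                raise ValueError(f"motif position {pos} has weight but no residues")
        if self.background is not None:
            total = sum(self.background.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"background frequencies sum to {total}, not 1")
        if self.protein_length[0] < 11:
            raise ValueError("proteins must be at least 11 residues long")

    def background_probs(self) -> tuple[str, np.ndarray]:
        if self.background is None:
            return AA20, np.full(len(AA20), 1.0 / len(AA20))
        letters = "".join(sorted(self.background))
        p = np.array([self.background[a] for a in letters])
        return letters, p / p.sum()


@dataclass
class SyntheticProteome:
    proteins: list[ProteinRecord]
    sites: list[PhosphoSite]
    truth: pd.DataFrame  # protein_id, position, label in {planted, background}

    def planted_windows(self) -> set[str]:
        from .sequence_library import window_at

        index = {p.id: p for p in self.proteins}
        return {
            window_at(index[row.protein_id], row.position)
            for row in self.truth.itertuples(index=False)
            if row.label == "planted"
        }


def _draw_flank(
    rng: np.random.Generator,
    spec: MotifSpec,
    position: int,
    planted: bool,
    letters: str,
    probs: np.ndarray,
) -> str:
    if planted and position in spec.motif:
        residues, weight = spec.motif[position]
        if weight > 0 and rng.random() < weight:
            return residues[rng.integers(len(residues))]
    return letters[rng.choice(len(letters), p=probs)]


def _window_string(rng, spec, planted, letters, probs) -> str:
    left = "".join(
        _draw_flank(rng, spec, j, planted, letters, probs) for j in range(-FLANK, 0)
    )
    right = "".join(
        _draw_flank(rng, spec, j, planted, letters, probs) for j in range(1, FLANK + 1)
    )
    return left + "Y" + right


def sample_windows(
    spec: MotifSpec, n: int, planted: bool, rng: np.random.Generator
) -> list[PeptideWindow]:
    """Draw ``n`` 11-mer windows directly (no host proteins), for unit tests
    and calibration studies."""
    letters, probs = spec.background_probs()
    return [
        PeptideWindow(_window_string(rng, spec, planted, letters, probs))
        for _ in range(n)
    ]


def generate_proteome(spec: MotifSpec) -> SyntheticProteome:
    """Generate the annotated proteome described by ``spec``.

    Each annotated site lives on its own protein (random background sequence
    with the site's window spliced in); ``n_background_proteins`` additional
    proteins carry no annotation and provide the background tyrosine class.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    letters, probs = spec.background_probs()
    lo, hi = spec.protein_length
    proteins: list[ProteinRecord] = []
    sites: list[PhosphoSite] = []
    truth_rows: list[dict] = []
    counter = 0

    def random_sequence(length: int) -> str:
        return "".join(letters[i] for i in rng.choice(len(letters), size=length, p=probs))

    for label, count in (("planted", spec.n_positive_sites),
                         ("background", spec.n_decoy_sites)):
        for _ in range(count):
            counter += 1
            pid, gene = f"SYN{counter:05d}", f"GENE{counter:05d}"
            length = int(rng.integers(lo, hi + 1))
            seq = list(random_sequence(length))
            position = int(rng.integers(FLANK + 1, length - FLANK + 1))  # 1-based
            window = _window_string(rng, spec, label == "planted", letters, probs)
            seq[position - 1 - FLANK : position + FLANK] = window
            proteins.append(ProteinRecord(pid, "".join(seq), gene=gene))
            sites.append(PhosphoSite(pid, position))
            truth_rows.append({"protein_id": pid, "position": position, "label": label})

    for _ in range(spec.n_background_proteins):
        counter += 1
        pid, gene = f"SYN{counter:05d}", f"GENE{counter:05d}"
        proteins.append(
            ProteinRecord(pid, random_sequence(int(rng.integers(lo, hi + 1))), gene=gene)
        )

    return SyntheticProteome(
        proteins=proteins,
        sites=sites,
        truth=pd.DataFrame(truth_rows, columns=["protein_id", "position", "label"]),
    )


def write_proteome(proteome: SyntheticProteome, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA + site TSV + truth TSV exactly as the readers expect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "proteins.fasta"
    with fasta.open("w") as fh:
        for p in proteome.proteins:
            fh.write(f">{p.id} {p.gene or ''}\n".rstrip() + "\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")
    sites = out / "sites.tsv"
    pd.DataFrame(
        [{"protein_id": s.protein_id, "position": s.position, "residue": s.residue}
         for s in proteome.sites]
    ).to_csv(sites, sep="\t", index=False, header=False)
    truth = out / "truth.tsv"
    proteome.truth.to_csv(truth, sep="\t", index=False)
    return {"fasta": fasta, "sites": sites, "truth": truth}


# ---------------------------------------------------------------------------
# Toy docked poses


def _pdb_line(serial, name, resname, chain, resnum, xyz, element) -> str:
    name_field = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:5d} {name_field}{resname:>4s} {chain}{resnum:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          {element:>2s}"
    )


def generate_toy_pose(
    py_in_site: bool = True,
    orientation: bool = True,
    hbond1: bool = True,
    hbond2: bool = True,
    hbond3: bool = True,
) -> str:
    """PDB text of an idealised complex in which each acceptance criterion
    holds or fails as requested, with >= 0.5 A margin either way.

    Chain A: Arg-47, Asp-48 (with carboxylate OD1/OD2) and a glycine P-loop
    at residues 214-221 (non-collinear Calpha trace, so superposition is well
    posed).  Chain B: a 5-residue peptide, phosphotyrosine (PTR, residue 3)
    in the middle.  The all-true pose doubles as the reference complex.
    """
    # P-loop Calpha centroid of this scaffold sits at (0, 0, 1.05)
    lines = ["REMARK  synthetic toy phosphatase-peptide pose"]
    serial = 0

    def add(name, resname, chain, resnum, xyz, element=None):
        nonlocal serial
        serial += 1
        element = element or name[0]
        lines.append(_pdb_line(serial, name, resname, chain, resnum, xyz, element))

    # chain A: Arg-47 / Asp-48
    add("N", "ARG", "A", 47, (-3.0, 6.0, 3.0))
    add("CA", "ARG", "A", 47, (-3.0, 8.0, 3.0))
    add("C", "ARG", "A", 47, (-2.0, 9.0, 3.0))
    add("O", "ARG", "A", 47, (-2.0, 10.2, 3.0))
    add("N", "ASP", "A", 48, (-1.0, 9.0, 3.0))
    add("CA", "ASP", "A", 48, (0.0, 8.0, 3.0))
    add("C", "ASP", "A", 48, (1.2, 9.0, 3.0))
    add("O", "ASP", "A", 48, (1.2, 10.2, 3.0))
    add("CG", "ASP", "A", 48, (0.3, 6.5, 3.0))
    add("OD1", "ASP", "A", 48, (0.0, 5.0, 3.0))
    add("OD2", "ASP", "A", 48, (1.0, 5.5, 3.0))
    # chain A: P-loop glycines 214-221 (slightly twisted line along x)
    for k in range(214, 222):
        x = (k - 217.5) * 1.9
        z = 0.3 * (k - 214)
        add("N", "GLY", "A", k, (x - 0.5, 0.8, z))
        add("CA", "GLY", "A", k, (x, 0.0, z))
        add("C", "GLY", "A", k, (x + 0.5, 0.8, z))

    # chain B peptide: residues 1..5, pY at 3
    ca1 = (-4.0, 3.0, 5.0) if orientation else (4.0, 3.0, 5.0)
    ca5 = (4.0, 3.0, 5.0) if orientation else (-4.0, 3.0, 5.0)
    o1 = (-3.0, 8.9, 3.0) if hbond3 else (-3.0, 12.0, 3.0)   # vs Arg-47 N at 2.9/6.0 A
    n3 = (0.0, 7.9, 3.0) if hbond1 else (0.0, 10.5, 3.0)     # vs Asp-48 OD1 at 2.9 A
    n4 = (1.0, 8.4, 3.0) if hbond2 else (1.0, 10.5, 3.0)     # vs Asp-48 OD2 at 2.9 A
    p3 = (0.0, 1.0, 1.5) if py_in_site else (0.0, 12.0, 1.5)  # vs pocket centroid

    add("N", "GLY", "B", 1, (-4.5, 2.2, 5.0))
    add("CA", "GLY", "B", 1, ca1)
    add("C", "GLY", "B", 1, (-3.5, 9.8, 3.5))
    add("O", "GLY", "B", 1, o1)
    add("N", "ALA", "B", 2, (-2.5, 2.2, 5.0))
    add("CA", "ALA", "B", 2, (-2.0, 3.0, 5.0))
    add("C", "ALA", "B", 2, (-1.5, 3.8, 5.0))
    add("O", "ALA", "B", 2, (-1.5, 5.0, 5.0))
    add("N", "PTR", "B", 3, n3)
    add("CA", "PTR", "B", 3, (0.0, 3.0, 5.0))
    add("C", "PTR", "B", 3, (0.5, 3.8, 5.0))
    add("O", "PTR", "B", 3, (0.5, 5.0, 5.0))
    add("P", "PTR", "B", 3, p3, "P")
    add("N", "ALA", "B", 4, n4)
    add("CA", "ALA", "B", 4, (2.0, 3.0, 5.0))
    add("C", "ALA", "B", 4, (2.5, 3.8, 5.0))
    add("O", "ALA", "B", 4, (2.5, 5.0, 5.0))
    add("N", "GLY", "B", 5, (3.5, 2.2, 5.0))
    add("CA", "GLY", "B", 5, ca5)
    add("C", "GLY", "B", 5, (4.5, 3.8, 5.0))
    add("O", "GLY", "B", 5, (4.5, 5.0, 5.0))
    lines.append("END")
    return "\n".join(lines) + "\n"
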