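"""Human-readable output: structure panels and the chemical-space projection.

The structure grid shows the base molecule next to each selected
counterfactual with the atoms that differ highlighted.  "Differ" is decided
by maximum-common-substructure comparison: atoms of the counterfactual
outside the MCS with the base are the modification.  The projection scatter
is a principal-coordinates embedding of the Tanimoto distance matrix,
colored by predictor output, with the base and the chosen counterfactuals
annotated.

Rendering is strictly best-effort: any drawing failure degrades to
tables-only output with a warning, never an error.
"""

from __future__ import annotations

import warnings
from pathlib import Path

from rdkit import Chem
from rdkit.Chem import Draw, rdFMCS

from .engine import ExplanationResult, project_space

__all__ = ["differing_atoms", "render_structure_grid", "render_projection", "render_report"]


def differing_atoms(base: Chem.Mol, other: Chem.Mol,
                    timeout: int = 5) -> list[int]:
    """Atom indices of ``other`` not covered by its MCS with ``base``."""
    res = rdFMCS.FindMCS([base, other], timeout=timeout)
    if res.canceled or not res.smartsString:
        return list(range(other.GetNumAtoms()))
    query = Chem.MolFromSmarts(res.smartsString)
    match = other.GetSubstructMatch(query)
    return [i for i in range(other.GetNumAtoms()) if i not in set(match)]


def render_structure_grid(result: ExplanationResult, out_path: str | Path) -> Path:
    """SVG grid: base plus counterfactuals, modified atoms highlighted."""
    out_path = Path(out_path)
    base_mol = result.base.record.mol
    mols = [base_mol]
    highlights: list[list[int]] = [[]]
    legends = [f"base  f̂={result.base.output}"]
    for i, cand in enumerate(result.counterfactuals, start=1):
        mol = cand.record.mol
        mols.append(mol)
        highlights.append(differing_atoms(base_mol, mol))
        arrow = {1: "↑", -1: "↓", 0: ""}[cand.direction]
        legends.append(
            f"counterfactual {i}{arrow}  f̂={cand.output}  s={cand.similarity:.2f}"
        )
    svg = Draw.MolsToGridImage(
        mols, legends=legends, highlightAtomLists=highlights,
        molsPerRow=min(4, len(mols)), subImgSize=(250, 220), useSVG=True,
    )
    if hasattr(svg, "data"):  # notebook wrapper
        svg = svg.data
    out_path.write_text(svg)
    return out_path


def render_projection(result: ExplanationResult, out_path: str | Path) -> Path:
    """Scatter of the 2-D chemical-space embedding, colored by output."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_path = Path(out_path)
    points = [result.base] + list(result.all_candidates)
    coords = project_space(points)
    outputs = [float(p.output) for p in points]
    fig, ax = plt.subplots(figsize=(6, 5))
    sc = ax.scatter(coords[1:, 0], coords[1:, 1], c=outputs[1:], s=12,
                    cmap="viridis", alpha=0.7, linewidths=0)
    ax.scatter([coords[0, 0]], [coords[0, 1]], marker="*", s=220,
               c="crimson", edgecolors="black", label="base", zorder=3)
    chosen = {c.record.canonical_smiles for c in result.counterfactuals}
    for i, p in enumerate(points[1:], start=1):
        if p.record.canonical_smiles in chosen:
            ax.scatter([coords[i, 0]], [coords[i, 1]], marker="o", s=90,
                       facecolors="none", edgecolors="crimson", zorder=3)
    fig.colorbar(sc, ax=ax, label="predictor output")
    ax.set_xlabel("PC 1")
    ax.set_ylabel("PC 2")
    ax.legend(loc="best")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def render_report(result: ExplanationResult, out_dir: str | Path) -> list[Path]:
    """Write all graphical artifacts; failures degrade to a warning."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if result.counterfactuals:
        try:
            written.append(render_structure_grid(result, out_dir / "counterfactuals.svg"))
        except Exception as exc:
            warnings.warn(f"structure grid rendering failed: {exc}", stacklevel=2)
    if len(result.all_candidates) + 1 >= 3:
        try:
            written.append(render_projection(result, out_dir / "chemical_space.png"))
        except Exception as exc:
            warnings.warn(f"projection rendering failed: {exc}", stacklevel=2)
    return written
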