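"""MS/MS molecular networking.

Nodes are tandem mass spectra; two spectra are connected when their fragment
patterns are similar enough that they plausibly share a scaffold — here, a
spectral cosine above a cut-off (default > 0.7) *and* a minimum number of
matched fragment peaks (default >= 6).  Connected components of the resulting
graph suggest compound families; nodes matching a spectral library of known
natural products are annotated so novel chemistry stands out.

Peak matching pairs fragments within a mass tolerance greedily by descending
intensity product, each peak used at most once.  Intensities are square-root
transformed before the cosine by default (standard networking practice, damps
base-peak dominance); raw intensities are available via a flag.  An optional
"modified cosine" additionally allows peak pairs offset by the precursor mass
difference, linking derivatives that differ by a neutral loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

__all__ = [
    "MsmsSpectrum",
    "SpectralEdge",
    "SpectralNetwork",
    "read_mgf",
    "write_mgf",
    "match_fragments",
    "spectral_cosine",
    "build_network",
    "annotate",
    "export_graph",
]


@dataclass(frozen=True)
class MsmsSpectrum:
    """A centroided MS/MS spectrum: precursor m/z plus (mz, intensity) peaks."""

    spectrum_id: str
    precursor_mz: float
    peaks: np.ndarray  # shape (n, 2): columns m/z, intensity; sorted by m/z
    name: str | None = None  # library compound label, if any

    def __post_init__(self) -> None:
        pk = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if np.any(pk[:, 1] <= 0):
            raise ValueError(f"spectrum {self.spectrum_id}: intensities must be > 0")
        order = np.argsort(pk[:, 0], kind="stable")
        object.__setattr__(self, "peaks", pk[order])

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class SpectralEdge:
    a: str
    b: str
    cosine: float
    matched_fragments: int


@dataclass(frozen=True)
class SpectralNetwork:
    graph: nx.Graph  # nodes: spectrum ids with attrs; edges with cosine/matched

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]


def read_mgf(path, intensity_floor: float = 1000.0) -> list[MsmsSpectrum]:
    """Parse an MGF file (BEGIN IONS / PEPMASS / peak lines / END IONS).

    Peaks strictly below ``intensity_floor`` are removed at read time
    (mirroring an absolute-intensity conversion filter); spectra left with no
    peaks are dropped.  Malformed blocks raise with the offending line number.
    """
    spectra: list[MsmsSpectrum] = []
    block: dict | None = None
    n_anon = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                if block is not None:
                    raise ValueError(f"{path}:{lineno}: nested BEGIN IONS")
                block = {"peaks": [], "params": {}}
            elif line == "END IONS":
                if block is None:
                    raise ValueError(f"{path}:{lineno}: END IONS without BEGIN IONS")
                params = block["params"]
                if "PEPMASS" not in params:
                    raise ValueError(f"{path}:{lineno}: spectrum block missing PEPMASS")
                peaks = [(mz, i) for mz, i in block["peaks"] if i >= intensity_floor]
                if peaks:
                    n_anon += 1
                    spectra.append(
                        MsmsSpectrum(
                            spectrum_id=params.get("TITLE", f"spectrum_{n_anon}"),
                            precursor_mz=float(params["PEPMASS"].split()[0]),
                            peaks=np.array(peaks),
                            name=params.get("NAME"),
                        )
                    )
                block = None
            elif block is None:
                continue  # header junk between blocks is tolerated
            elif "=" in line:
                key, _, val = line.partition("=")
                block["params"][key.upper()] = val
            else:
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: malformed peak line {line!r}")
                try:
                    block["peaks"].append((float(parts[0]), float(parts[1])))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed peak line {line!r}") from exc
    if block is not None:
        raise ValueError(f"{path}: unterminated BEGIN IONS block")
    return spectra


def write_mgf(spectra: list[MsmsSpectrum], path) -> None:
    """Write spectra as MGF; peaks at 6 decimals so read/write round-trips."""
    with open(path, "w") as fh:
        for sp in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={sp.spectrum_id}\n")
            fh.write(f"PEPMASS={sp.precursor_mz:.6f}\n")
            if sp.name:
                fh.write(f"NAME={sp.name}\n")
            for mz, inten in sp.peaks:
                fh.write(f"{mz:.6f} {inten:.6f}\n")
            fh.write("END IONS\n\n")


def _tol_da(mz: float, tol_da: float | None, tol_ppm: float | None) -> float:
    if tol_ppm is not None:
        return mz * tol_ppm * 1e-6
    return tol_da if tol_da is not None else 0.05


def match_fragments(
    a: MsmsSpectrum,
    b: MsmsSpectrum,
    tol_da: float | None = 0.05,
    tol_ppm: float | None = None,
    precursor_shift: bool = False,
) -> list[tuple[int, int]]:
    """Greedy one-to-one fragment pairing within a mass tolerance.

    Candidate pairs (within tolerance; with ``precursor_shift`` also pairs
    offset by the precursor mass difference) are sorted by intensity product
    descending and accepted when both peaks are still unused.  Returns index
    pairs into ``a.peaks`` / ``b.peaks``.
    """
    if a.n_peaks == 0 or b.n_peaks == 0:
        return []
    shifts = [0.0]
    if precursor_shift:
        shifts.append(b.precursor_mz - a.precursor_mz)
    cands: list[tuple[float, int, int]] = []
    for i, (mza, ia) in enumerate(a.peaks):
        for j, (mzb, ib) in enumerate(b.peaks):
            for sh in shifts:
                if abs(mza + sh - mzb) <= _tol_da(mza, tol_da, tol_ppm):
                    cands.append((ia * ib, i, j))
                    break
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in cands:
        if i not in used_a and j not in used_b:
            pairs.append((i, j))
            used_a.add(i)
            used_b.add(j)
    return sorted(pairs)


def spectral_cosine(
    a: MsmsSpectrum,
    b: MsmsSpectrum,
    tol_da: float | None = 0.05,
    tol_ppm: float | None = None,
    sqrt_intensity: bool = True,
    precursor_shift: bool = False,
) -> tuple[float, int]:
    """Spectral cosine over matched peak pairs, and the matched count.

    Intensities (optionally square-rooted) are normalised to unit vector norm
    over the *full* spectrum, so unmatched peaks dilute the score; the cosine
    of a spectrum with itself is exactly 1.
    """
    if a.n_peaks == 0 or b.n_peaks == 0:
        raise ValueError("cannot compute cosine of an empty spectrum")
    wa = np.sqrt(a.peaks[:, 1]) if sqrt_intensity else a.peaks[:, 1].copy()
    wb = np.sqrt(b.peaks[:, 1]) if sqrt_intensity else b.peaks[:, 1].copy()
    wa /= np.linalg.norm(wa)
    wb /= np.linalg.norm(wb)
    pairs = match_fragments(a, b, tol_da=tol_da, tol_ppm=tol_ppm, precursor_shift=precursor_shift)
    cos = float(sum(wa[i] * wb[j] for i, j in pairs))
    return min(cos, 1.0), len(pairs)


def build_network(
    spectra: list[MsmsSpectrum],
    cosine_cut: float = 0.7,
    min_matched: int = 6,
    tol_da: float | None = 0.05,
    tol_ppm: float | None = None,
    sqrt_intensity: bool = True,
    precursor_shift: bool = False,
) -> SpectralNetwork:
    """Connect spectra with cosine > cosine_cut AND matched >= min_matched.

    Both conditions must hold (a high cosine on five shared fragments is not
    enough).  Isolated nodes are retained and flagged.
    """
    if not spectra:
        raise ValueError("need at least 1 spectrum")
    g = nx.Graph()
    for sp in spectra:
        g.add_node(sp.spectrum_id, precursor_mz=float(sp.precursor_mz),
                   n_peaks=int(sp.n_peaks))
    for i in range(len(spectra)):
        for j in range(i + 1, len(spectra)):
            cos, matched = spectral_cosine(
                spectra[i], spectra[j], tol_da=tol_da, tol_ppm=tol_ppm,
                sqrt_intensity=sqrt_intensity, precursor_shift=precursor_shift,
            )
            if cos > cosine_cut and matched >= min_matched:
                g.add_edge(spectra[i].spectrum_id, spectra[j].spectrum_id,
                           cosine=float(cos), matched=int(matched))
    for node in g.nodes:
        g.nodes[node]["isolated"] = g.degree[node] == 0
    return SpectralNetwork(graph=g)


def annotate(
    net: SpectralNetwork,
    spectra: list[MsmsSpectrum],
    library: list[MsmsSpectrum],
    cosine_cut: float = 0.7,
    min_matched: int = 6,
    tol_da: float | None = 0.05,
    tol_ppm: float | None = None,
) -> SpectralNetwork:
    """Annotate nodes with the best library match passing the same edge rule.

    The highest-cosine library compound wins; exact ties report every tied
    name joined by ';'.  Nodes without a qualifying match are untouched.
    """
    by_id = {sp.spectrum_id: sp for sp in spectra}
    g = net.graph.copy()
    for node in g.nodes:
        sp = by_id.get(node)
        if sp is None:
            continue
        best: list[tuple[float, str]] = []
        for lib in library:
            cos, matched = spectral_cosine(sp, lib, tol_da=tol_da, tol_ppm=tol_ppm)
            if cos > cosine_cut and matched >= min_matched:
                best.append((cos, lib.name or lib.spectrum_id))
        if best:
            top = max(c for c, _ in best)
            names = sorted({nm for c, nm in best if abs(c - top) < 1e-12})
            g.nodes[node]["annotation"] = ";".join(names)
            g.nodes[node]["annotation_cosine"] = float(top)
    return SpectralNetwork(graph=g)


def export_graph(net: SpectralNetwork, path, fmt: str = "graphml") -> None:
    """Export the network as GraphML or a TSV edge list."""
    if fmt == "graphml":
        nx.write_graphml(net.graph, path)
    elif fmt == "edge-list":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tcosine\tmatched\n")
            for a, b, data in net.graph.edges(data=True):
                fh.write(f"{a}\t{b}\t{data['cosine']:.6f}\t{data['matched']}\n")
    else:
        raise ValueError(f"unsupported format {fmt!r}; use 'graphml' or 'edge-list'")
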