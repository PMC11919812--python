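"""Geometric quality control of predicted isopeptide bonds.

Two orthogonal checks, both referenced to a library of known-good bond
geometries:

* the NZ-acyl-carbon bond length as a Z-score against the reference mean
  and standard deviation, flagged when |Z| strictly exceeds 4;
* three pseudo-dihedral angles along the cross-link chain
  CD-CE-NZ-C(acyl)-CB-CA, scored pairwise (phi/psi, omega/psi, omega/phi)
  by 2-D Gaussian kernel density estimates fitted per bond topology
  (CnaA-like, CnaB-like) - six models in total.  A pair is flagged when its
  log-likelihood falls below the 5th percentile of the reference sample's
  own likelihoods, so about 5% of reference geometries are outliers by
  construction.

The isopeptide C-N link is treated as a peptide-bond analogue: pseudo-omega
is the torsion about the acyl C-N bond, pseudo-phi precedes it on the
lysine arm and pseudo-psi follows it on the acceptor arm.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy.stats import gaussian_kde

from ._geom import dihedral
from .structure_io import Residue

ANGLE_PAIRS = (("phi", "psi"), ("omega", "psi"), ("omega", "phi"))
TOPOLOGIES = ("CnaA-like", "CnaB-like")
ZSCORE_CUTOFF = 4.0
_MIRROR_MARGIN = 20.0  # degrees within the +-180 cut that get mirrored
MIN_KDE_SAMPLES = 20


class GeometryError(Exception):
    pass


def acyl_carbon_name(acceptor_res_name: str) -> str:
    """The bond-accepting acyl carbon: CG for Asn/Asp, CD for Glu."""
    return "CD" if acceptor_res_name == "GLU" else "CG"


def bond_length(site: tuple[Residue, Residue, Residue]) -> float | None:
    """Euclidean NZ-acyl-carbon distance, or None when an atom is missing."""
    lys, _, acceptor = site
    nz = lys.coord("NZ")
    acyl = acceptor.coord(acyl_carbon_name(acceptor.res_name))
    if nz is None or acyl is None:
        return None
    return float(np.linalg.norm(nz - acyl))


def pseudo_dihedrals(site: tuple[Residue, Residue, Residue]) -> dict[str, float | None]:
    """Signed pseudo phi/psi/omega (degrees) along the cross-link chain.

    phi = CD-CE-NZ-C(acyl); omega = CE-NZ-C(acyl)-CB; psi = NZ-C(acyl)-CB-CA.
    Angles whose atoms are missing come back as None.
    """
    lys, _, acceptor = site
    acyl = acceptor.coord(acyl_carbon_name(acceptor.res_name))
    chain = {
        "CD": lys.coord("CD"),
        "CE": lys.coord("CE"),
        "NZ": lys.coord("NZ"),
        "C": acyl,
        "CB": acceptor.coord("CB"),
        "CA": acceptor.coord("CA"),
    }

    def _dih(names: tuple[str, str, str, str]) -> float | None:
        pts = [chain[n] for n in names]
        if any(p is None for p in pts):
            return None
        return dihedral(*pts)

    return {
        "phi": _dih(("CD", "CE", "NZ", "C")),
        "omega": _dih(("CE", "NZ", "C", "CB")),
        "psi": _dih(("NZ", "C", "CB", "CA")),
    }


def zscore(length: float, mean: float, sd: float) -> tuple[float, bool]:
    """Signed Z-score and outlier flag; outlier iff |z| strictly exceeds 4."""
    if sd <= 0:
        raise GeometryError("reference bond-length sd must be positive")
    z = (length - mean) / sd
    return float(z), bool(abs(z) > ZSCORE_CUTOFF)


def _circular_mean(angles_deg: np.ndarray) -> float:
    rad = np.radians(angles_deg)
    return float(np.degrees(np.arctan2(np.mean(np.sin(rad)), np.mean(np.cos(rad)))))


def _mirror_augment(points: np.ndarray, margin: float = _MIRROR_MARGIN) -> np.ndarray:
    """Duplicate samples lying within ``margin`` of the +-180 cut across it.

    Reduces wrap-around bias of a Euclidean KDE on circular data: density
    that a kernel leaks past the cut is compensated by its mirrored copy
    re-entering from the other side.
    """
    out = [points]
    for mask_dims in range(1, 4):
        shift = np.zeros((points.shape[0], 2))
        ok = np.ones(points.shape[0], dtype=bool)
        for d in range(2):
            if mask_dims & (1 << d):
                hi = points[:, d] > 180.0 - margin
                lo = points[:, d] < -180.0 + margin
                shift[hi, d] = -360.0
                shift[lo, d] = 360.0
                ok &= hi | lo
        if ok.any():
            out.append(points[ok] + shift[ok])
    return np.vstack(out)


class DihedralKDE:
    """2-D Gaussian KDE over one angle pair on the circle.

    Each dimension is first re-centered on its circular mean, so that a
    unimodal distribution sitting on the +-180 cut (e.g. trans omega) becomes
    contiguous before the Euclidean KDE sees it; without this the sample
    covariance - and with it Scott's-rule bandwidth - is inflated by the
    wrap-around.  Samples remaining within 20 degrees of the re-centered cut
    are additionally mirrored across it, and likelihoods are rescaled by
    (n_augmented / n_original) so the density still integrates to ~1 over
    one period.
    """

    def __init__(self, samples: np.ndarray):
        samples = np.asarray(samples, dtype=float)
        if samples.ndim != 2 or samples.shape[1] != 2:
            raise GeometryError("samples must have shape (n, 2)")
        if samples.shape[0] < MIN_KDE_SAMPLES:
            raise GeometryError(
                f"need >= {MIN_KDE_SAMPLES} samples to fit a KDE, got {samples.shape[0]}"
            )
        self.n_original = samples.shape[0]
        self.center = np.array([_circular_mean(samples[:, d]) for d in range(2)])
        shifted = self._to_frame(samples)
        augmented = _mirror_augment(shifted)
        self._kde = gaussian_kde(augmented.T)
        self._log_correction = float(np.log(augmented.shape[0] / self.n_original))
        self.train_log_likelihood = self.log_likelihood(samples)
        self.cutoff = float(np.percentile(self.train_log_likelihood, 5.0))

    def _to_frame(self, points: np.ndarray) -> np.ndarray:
        """Map angles into (-180, 180] around the fitted circular center."""
        shifted = points - self.center
        shifted = (shifted + 180.0) % 360.0 - 180.0
        shifted[shifted == -180.0] = 180.0
        return shifted

    @property
    def bandwidth_factor(self) -> float:
        return float(self._kde.factor)

    def log_likelihood(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return self._kde.logpdf(self._to_frame(points).T) + self._log_correction

    def is_outlier(self, point: np.ndarray) -> bool:
        return bool(self.log_likelihood(point)[0] < self.cutoff)


@dataclasses.dataclass
class GeometryReference:
    """Reference bond geometries and the six fitted KDE models."""

    bond_length_mean: float
    bond_length_sd: float
    kdes: dict[tuple[str, tuple[str, str]], DihedralKDE]

    @classmethod
    def fit(
        cls,
        bond_lengths: np.ndarray,
        dihedral_samples: dict[str, np.ndarray],
    ) -> "GeometryReference":
        """Fit from raw samples.

        ``dihedral_samples`` maps topology -> (n, 3) array of
        (phi, psi, omega) in degrees.
        """
        bond_lengths = np.asarray(bond_lengths, dtype=float)
        if bond_lengths.size < 2:
            raise GeometryError("need at least 2 bond-length samples")
        kdes = {}
        columns = {"phi": 0, "psi": 1, "omega": 2}
        for topology in TOPOLOGIES:
            if topology not in dihedral_samples:
                raise GeometryError(f"missing dihedral samples for {topology}")
            arr = np.asarray(dihedral_samples[topology], dtype=float)
            for pair in ANGLE_PAIRS:
                cols = [columns[name] for name in pair]
                kdes[(topology, pair)] = DihedralKDE(arr[:, cols])
        return cls(
            bond_length_mean=float(np.mean(bond_lengths)),
            bond_length_sd=float(np.std(bond_lengths, ddof=1)),
            kdes=kdes,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "GeometryReference":
        """Load the tabular reference resource.

        Schema: TSV with a header and columns topology, phi, psi, omega,
        bond_length - one row per curated reference bond.  A user-curated
        table of real bonds with the same columns can be dropped in.
        """
        rows = Path(path).read_text().splitlines()
        header = rows[0].split("\t")
        expected = ["topology", "phi", "psi", "omega", "bond_length"]
        if header != expected:
            raise GeometryError(f"{path}: expected columns {expected}, got {header}")
        lengths = []
        samples: dict[str, list] = {t: [] for t in TOPOLOGIES}
        for line in rows[1:]:
            if not line.strip():
                continue
            topology, phi, psi, omega, length = line.split("\t")
            if topology not in samples:
                raise GeometryError(f"{path}: unknown topology {topology!r}")
            samples[topology].append([float(phi), float(psi), float(omega)])
            lengths.append(float(length))
        return cls.fit(
            np.array(lengths), {t: np.array(v) for t, v in samples.items()}
        )


@dataclasses.dataclass
class GeometryReport:
    bond_length: float | None
    zscore: float | None
    zscore_outlier: bool
    dihedrals: dict[str, float | None]
    pair_likelihoods: dict[tuple[str, str], float | None]
    pair_outliers: dict[tuple[str, str], bool]
    overall_flag: str  # "ok" | "outlier"


def assess(
    site: tuple[Residue, Residue, Residue],
    topology: str,
    ref: GeometryReference,
) -> GeometryReport:
    """Full geometry report for one predicted bond.

    The KDE trio is selected by the topology of the closest template.  A
    measurement whose atoms are missing is skipped (reported as None) and
    does not flag; the overall flag is "outlier" iff any computed component
    flags.
    """
    length = bond_length(site)
    if length is not None:
        z, z_out = zscore(length, ref.bond_length_mean, ref.bond_length_sd)
    else:
        z, z_out = None, False
    angles = pseudo_dihedrals(site)
    likelihoods: dict[tuple[str, str], float | None] = {}
    outliers: dict[tuple[str, str], bool] = {}
    for pair in ANGLE_PAIRS:
        a, b = angles[pair[0]], angles[pair[1]]
        if a is None or b is None:
            likelihoods[pair] = None
            outliers[pair] = False
            continue
        kde = ref.kdes[(topology, pair)]
        ll = float(kde.log_likelihood(np.array([a, b]))[0])
        likelihoods[pair] = ll
        outliers[pair] = ll < kde.cutoff
    return GeometryReport(
        bond_length=length,
        zscore=z,
        zscore_outlier=z_out,
        dihedrals=angles,
        pair_likelihoods=likelihoods,
        pair_outliers=outliers,
        overall_flag=combine_flags(z_out, list(outliers.values())),
    )


def combine_flags(zscore_outlier: bool, pair_outliers: list[bool]) -> str:
    """Overall geometry verdict: outlier iff any component flags."""
    return "outlier" if (zscore_outlier or any(pair_outliers)) else "ok"
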