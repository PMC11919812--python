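"""Independent reference implementations used only to cross-check the
package.  Each oracle deliberately takes a different computational route
than the code it validates."""
from __future__ import annotations

import itertools

import numpy as np

# --- Kabsch superposition via explicit SVD (vs scipy align_vectors) ---------

def kabsch_rmsd_svd(p: np.ndarray, q: np.ndarray) -> float:
    p = np.asarray(p, float) - np.mean(p, axis=0)
    q = np.asarray(q, float) - np.mean(q, axis=0)
    h = q.T @ p
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = p - q @ rot.T
    return float(np.sqrt(np.sum(diff * diff) / p.shape[0]))


# --- brute-force template matcher -------------------------------------------

def brute_force_matches(structure, library, config):
    """Enumerate every type-compatible residue triple for every template and
    score it directly; returns {(template_id, site_key): rmsd}."""
    from isopeptide_detect.templates import ROLES

    sym = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
    results: dict[tuple, float] = {}
    residues = [r for r in structure.iter_residues() if r.is_standard]
    for template in library:
        role_info = {}
        for role in ROLES:
            names = [a.atom_name for a in template.role_atoms(role)]
            res_name = template.res_name(role)
            maps = [{n: n for n in names}]
            pair = sym.get(res_name)
            if pair and pair[0] in names and pair[1] in names:
                swapped = dict(maps[0])
                swapped[pair[0]], swapped[pair[1]] = pair[1], pair[0]
                maps.append(swapped)
            role_info[role] = (res_name, names, maps)
        t_coords = template.coords()
        nt = len(t_coords)
        t_dist = np.linalg.norm(t_coords[:, None] - t_coords[None, :], axis=-1)
        for triple in itertools.permutations(residues, 3):
            ok_types = all(
                triple[k].res_name == role_info[role][0]
                for k, role in enumerate(ROLES)
            )
            if not ok_types:
                continue
            best = None
            for maps in itertools.product(
                *(role_info[role][2] for role in ROLES)
            ):
                coords = []
                missing = False
                for k, role in enumerate(ROLES):
                    for name in role_info[role][1]:
                        atom = triple[k].atoms.get(maps[k][name])
                        if atom is None:
                            missing = True
                            break
                        coords.append(atom.coord)
                    if missing:
                        break
                if missing:
                    continue
                coords = np.array(coords)
                d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
                if np.max(np.abs(d - t_dist)) > config.distance_tolerance:
                    continue
                rmsd = kabsch_rmsd_svd(t_coords, coords)
                if rmsd <= config.rmsd_cutoff and (best is None or rmsd < best):
                    best = rmsd
            if best is not None:
                key = (template.id, frozenset(r.key for r in triple))
                if key not in results or best < results[key]:
                    results[key] = best
    return results


# --- dihedral via an unrelated atan2 formulation ----------------------------

def dihedral_atan2(p0, p1, p2, p3) -> float:
    """Torsion angle from the cross-product normals directly."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


# --- two-overlapping-spheres SASA closed form -------------------------------

def two_sphere_exposed_area(radius: float, center_distance: float) -> float:
    """Exposed area of each of two equal spheres of ``radius`` whose centers
    are ``center_distance`` apart (spherical-cap subtraction)."""
    if center_distance >= 2 * radius:
        return 4.0 * np.pi * radius**2
    cap_height = radius - center_distance / 2.0
    return 4.0 * np.pi * radius**2 - 2.0 * np.pi * radius * cap_height


# --- direct Gaussian kernel sum for the dihedral KDE ------------------------

def kde_log_likelihood_direct(kde, points: np.ndarray) -> np.ndarray:
    """Recompute a fitted DihedralKDE's log-likelihood by an explicit
    mixture-of-Gaussians sum over its (augmented) training points, using the
    same bandwidth matrix but none of scipy's evaluation code."""
    from scipy.special import logsumexp

    cov = kde._kde.covariance          # (2, 2) bandwidth matrix
    data = kde._kde.dataset.T          # (m, 2) augmented training points
    n_orig = kde.n_original
    inv = np.linalg.inv(cov)
    log_norm = -np.log(2.0 * np.pi) - 0.5 * np.log(np.linalg.det(cov))
    points = kde._to_frame(np.atleast_2d(np.asarray(points, float)))
    out = np.empty(points.shape[0])
    for i, x in enumerate(points):
        diff = data - x
        expo = -0.5 * np.einsum("ij,jk,ik->i", diff, inv, diff)
        out[i] = log_norm + logsumexp(expo) - np.log(n_orig)
    return out


# --- Needleman-Wunsch / Gotoh identity oracle -------------------------------

def nw_identity(a: str, b: str, matrix, gap_open: int = 10, gap_extend: int = 1) -> float:
    """Percent identity of the optimal end-gap-free global alignment,
    computed by an explicit affine-gap dynamic program with traceback."""
    la, lb = len(a), len(b)
    neg = -10**9
    score = lambda x, y: matrix[x, y]
    m = np.full((la + 1, lb + 1), neg, float)   # match state
    ix = np.full((la + 1, lb + 1), neg, float)  # gap in b (moving along a)
    iy = np.full((la + 1, lb + 1), neg, float)  # gap in a
    m[0, 0] = 0.0
    # free end gaps: starting gaps cost nothing
    ix[1:, 0] = 0.0
    iy[0, 1:] = 0.0
    ptr_m = np.zeros((la + 1, lb + 1), int)
    ptr_x = np.zeros((la + 1, lb + 1), int)
    ptr_y = np.zeros((la + 1, lb + 1), int)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = score(a[i - 1], b[j - 1])
            cand = (m[i - 1, j - 1], ix[i - 1, j - 1], iy[i - 1, j - 1])
            k = int(np.argmax(cand))
            m[i, j] = cand[k] + s
            ptr_m[i, j] = k
            cand = (m[i - 1, j] - gap_open, ix[i - 1, j] - gap_extend)
            k = int(np.argmax(cand))
            ix[i, j] = cand[k]
            ptr_x[i, j] = k
            cand = (m[i, j - 1] - gap_open, iy[i, j - 1] - gap_extend)
            k = int(np.argmax(cand))
            iy[i, j] = cand[k]
            ptr_y[i, j] = k
    # free end gaps: best score anywhere on the last row/column
    best = (neg, None)
    for i in range(la + 1):
        for state, val in ((0, m[i, lb]), (1, ix[i, lb]), (2, iy[i, lb])):
            if val > best[0]:
                best = (val, (i, lb, state))
    for j in range(lb + 1):
        for state, val in ((0, m[la, j]), (1, ix[la, j]), (2, iy[la, j])):
            if val > best[0]:
                best = (val, (la, j, state))
    i, j, state = best[1]
    # alignment length includes the trailing free end gaps
    length = max(la - i, lb - j)
    ident = 0
    while i > 0 or j > 0:
        if state == 0:
            if i == 0 or j == 0:
                break
            if a[i - 1] == b[j - 1]:
                ident += 1
            state = ptr_m[i, j]
            i, j = i - 1, j - 1
        elif state == 1:
            if i == 0:
                break
            nxt = ptr_x[i, j]
            state = 0 if nxt == 0 else 1
            i -= 1
        else:
            if j == 0:
                break
            nxt = ptr_y[i, j]
            state = 0 if nxt == 0 else 2
            j -= 1
        length += 1
    length += max(i, j)  # leading free end gaps
    return 100.0 * ident / length


# --- logistic regression by generic numerical optimization ------------------

def logistic_fit_gd(x: np.ndarray, y: np.ndarray, c: float = 1.0):
    """L2-regularized logistic regression fitted with scipy's BFGS on the
    explicit objective (the regularizer excludes the intercept, matching the
    common convention)."""
    from scipy.optimize import minimize

    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def objective(params):
        w, b = params[:-1], params[-1]
        z = x @ w + b
        # log(1 + exp(-yz)) with y in {-1, +1}, numerically stable
        yy = 2 * y - 1
        loss = np.sum(np.logaddexp(0.0, -yy * z))
        return loss / c + 0.5 * np.dot(w, w)

    res = minimize(objective, np.zeros(x.shape[1] + 1), method="BFGS")
    return res.x[:-1], res.x[-1]
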