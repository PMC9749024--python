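"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (explicit loops, textbook formulas,
hand-rolled SVD Kabsch) and shares no code with the package.
"""

from __future__ import annotations

import numpy as np


def kabsch_aligned_rmsd(frame: np.ndarray, reference: np.ndarray,
                        anchor_idx: np.ndarray, ligand_idx: np.ndarray) -> float:
    """Aligned ligand RMSD (Å) via an explicit SVD Kabsch superposition."""
    p = frame[anchor_idx] - frame[anchor_idx].mean(axis=0)
    q = reference[anchor_idx] - reference[anchor_idx].mean(axis=0)
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    moved = (frame[ligand_idx] - frame[anchor_idx].mean(axis=0)) @ rot.T \
        + reference[anchor_idx].mean(axis=0)
    total = 0.0
    for a, b in zip(moved, reference[ligand_idx]):
        total += sum((a[k] - b[k]) ** 2 for k in range(3))
    return float(np.sqrt(total / len(ligand_idx)))


def brute_contact_count(frame, protein_heavy, ligand_heavy, cutoff, box=None):
    count = 0
    for i in protein_heavy:
        for j in ligand_heavy:
            d = frame[i] - frame[j]
            if box is not None:
                for k in range(3):
                    d[k] -= box[k] * round(d[k] / box[k])
            if np.sqrt(np.dot(d, d)) <= cutoff:
                count += 1
    return count


def brute_hbonds(frame, atoms, d_cutoff, angle_cutoff):
    """Triple loop over (donor, hydrogen, acceptor) across the interface."""
    polar = {"N", "O", "S"}
    found = set()
    for donor_role, acceptor_role in (("protein", "ligand"), ("ligand", "protein")):
        donors = [a for a in atoms if a.role == donor_role and a.element in polar]
        hydros = [a for a in atoms if a.role == donor_role and a.element == "H"]
        accs = [a for a in atoms if a.role == acceptor_role and a.element in polar]
        for h in hydros:
            # covalent attachment: nearest donor-side polar atom within 1.25 A
            best, bestd = None, 1.25
            for d in donors:
                dist = np.linalg.norm(frame[h.index] - frame[d.index])
                if dist <= bestd:
                    best, bestd = d, dist
            if best is None:
                continue
            for acc in accs:
                if acc.index == best.index:
                    continue
                if np.linalg.norm(frame[best.index] - frame[acc.index]) > d_cutoff:
                    continue
                v1 = frame[best.index] - frame[h.index]
                v2 = frame[acc.index] - frame[h.index]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= angle_cutoff:
                    found.add((best.index, h.index, acc.index))
    return found


def brute_anchor_selection(coords, calpha_idx, ligand_heavy_idx, cutoff):
    """Double loop over (Calpha, ligand heavy) pairs."""
    selected = []
    for i in calpha_idx:
        for j in ligand_heavy_idx:
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                selected.append(i)
                break
    return selected


def textbook_pearson(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))


def enumerate_wilcoxon(a, b):
    """Exact two-sided signed-rank p by enumerating every sign assignment."""
    import itertools

    from scipy.stats import rankdata

    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    s = ranks.sum()
    stat = min(w_plus, s - w_plus)
    lo, hi = min(w_plus, s - w_plus), max(w_plus, s - w_plus)
    hits = 0
    for signs in itertools.product((0, 1), repeat=len(d)):
        t = sum(r for sgn, r in zip(signs, ranks) if sgn)
        if t <= lo + 1e-9 or t >= hi - 1e-9:
            hits += 1
    return stat, hits / 2.0 ** len(d)


def random_rigid_transform(rng):
    """A uniform-ish random proper rotation and a random translation."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.uniform(-20, 20, 3)
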