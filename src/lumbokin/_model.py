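"""Internal reduced-order numerical model of the lumbar chain.

Each motion segment is condensed to six relative degrees of freedom
(translation mm, rotation-vector rad of the upper vertebra about the disc
centroid, in the disc-local frame).  The restoring behaviour sums

* a homogenized annulus-ground-substance foundation (6x6 diagonal
  stiffness from the confined modulus, shear modulus and the elliptical
  section properties),
* a nucleus cavity model: the nucleus bulk stiffness in series with the
  hoop confinement of the fibre-reinforced annulus wall, acting on the
  endplate area (this reproduces incompressibility as a penalty and the
  compressible behaviour of degenerated / comparison nuclei),
* explicit tension-only fibre trusses sampled over the five annulus layers,
* explicit tension-only bilinear ligament strands,
* unilateral facet penalty contacts (double-sided tangential restraint of
  the articular pair).

Everything here is energy-based and fully vectorized over a leading batch
axis so the solver can finite-difference gradients and Hessians in single
batched calls.  Units: N, mm, rad internally (energies in N*mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._rotations import matrix_to_rotvec, rotvec_to_matrix
from .materials import ElasticNucleus, MaterialCard, MooneyRivlinNucleus

__all__ = ["JointModel", "ChainModel", "ResolvedLoad"]


def _relu(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, None)


@dataclass
class JointModel:
    """Batched energy model of one motion segment in disc-local coordinates."""

    level: str
    height: float
    center_world: np.ndarray           # (3,)
    axes_world: np.ndarray             # (3,3), columns local->world
    K6: np.ndarray                     # (6,) diagonal foundation stiffness
    nucleus_area: float
    nucleus_volume: float
    confinement_modulus: float         # c_b, MPa
    nucleus_bulk: float                # K_n (penalty bulk for incompressible)
    fib_pl: np.ndarray                 # (nf,3) lower endpoints
    fib_pu: np.ndarray                 # (nf,3) upper endpoints (move with upper)
    fib_L0: np.ndarray                 # (nf,)
    fib_EA: np.ndarray                 # (nf,) N
    fib_pre: np.ndarray                # (nf,) strain offsets (<=0 slack)
    fib_layer: np.ndarray              # (nf,) 1..5
    lig_names: tuple[str, ...]
    lig_al: np.ndarray                 # (nl,3)
    lig_au: np.ndarray                 # (nl,3)
    lig_L0: np.ndarray
    lig_area: np.ndarray
    lig_E1: np.ndarray
    lig_E2: np.ndarray
    lig_ts: np.ndarray
    lig_pre: np.ndarray
    fac_p: np.ndarray                  # (nc,3)
    fac_n: np.ndarray                  # (nc,3)
    fac_g0: np.ndarray                 # (nc,)
    fac_k: np.ndarray                  # (nc,)

    @property
    def series_bulk(self) -> float:
        """Effective axial bulk of nucleus + confinement in series, MPa."""
        return self.nucleus_bulk * self.confinement_modulus / (
            self.nucleus_bulk + self.confinement_modulus
        )

    # -- batched energies -------------------------------------------------
    def _truss_strain(self, R: np.ndarray, t: np.ndarray, pl, pu, L0) -> np.ndarray:
        cur = np.einsum("...ij,nj->...ni", R, pu) + t[..., None, :] - pl
        L = np.linalg.norm(cur, axis=-1)
        return (L - L0) / L0

    def energy_terms(self, R: np.ndarray, t: np.ndarray, theta: np.ndarray) -> dict:
        """Per-constituent energies, each shaped like the batch."""
        q6 = np.concatenate([t, theta], axis=-1)
        e_annulus = 0.5 * np.einsum("...i,i,...i->...", q6, self.K6, q6)

        dv = self.nucleus_area * t[..., 2]          # cavity volume change, mm^3
        e_nucleus = 0.5 * self.series_bulk * dv**2 / self.nucleus_volume

        eps_f = self._truss_strain(R, t, self.fib_pl, self.fib_pu, self.fib_L0)
        e_fib = 0.5 * self.fib_EA * self.fib_L0 * _relu(eps_f + self.fib_pre) ** 2
        e_fibers = e_fib.sum(axis=-1)

        eps_l = self._truss_strain(R, t, self.lig_al, self.lig_au, self.lig_L0)
        eps_eff = _relu(eps_l + self.lig_pre)
        lo = np.minimum(eps_eff, self.lig_ts)
        hi = _relu(eps_eff - self.lig_ts)
        dens = 0.5 * self.lig_E1 * lo**2 + self.lig_E1 * self.lig_ts * hi + 0.5 * self.lig_E2 * hi**2
        e_ligs = (self.lig_area * self.lig_L0 * dens).sum(axis=-1)

        disp = np.einsum("...ij,nj->...ni", R, self.fac_p) + t[..., None, :] - self.fac_p
        s = np.einsum("...ni,ni->...n", disp, self.fac_n)
        pen = _relu(s - self.fac_g0) ** 2 + _relu(-s - self.fac_g0) ** 2
        e_fac = (0.5 * self.fac_k * pen).sum(axis=-1)

        return {
            "annulus": e_annulus,
            "nucleus": e_nucleus,
            "fibers": e_fibers,
            "ligaments": e_ligs,
            "facets": e_fac,
        }

    def energy(self, R: np.ndarray, t: np.ndarray, theta: np.ndarray) -> np.ndarray:
        terms = self.energy_terms(R, t, theta)
        return sum(terms.values())

    def energy_from_q(self, q: np.ndarray) -> np.ndarray:
        """Energy from (…, 6) local state (t mm, theta rad)."""
        q = np.asarray(q, dtype=float)
        t, theta = q[..., :3], q[..., 3:]
        return self.energy(rotvec_to_matrix(theta), t, theta)

    # -- gradients (exact at tension-onset kinks) -------------------------
    _H_T = 1e-5   # FD half-step for the smooth geometric sensitivities, mm
    _H_R = 1e-6   # rad

    def _perturbed_states(self, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        steps = np.array([self._H_T] * 3 + [self._H_R] * 3)
        Q = np.repeat(q[None], 12, axis=0)
        idx = np.arange(6)
        Q[2 * idx, idx] += steps
        Q[2 * idx + 1, idx] -= steps
        return Q, steps

    def constituent_gradients(self, q: np.ndarray) -> dict[str, np.ndarray]:
        """dU/dq per constituent at a local state (t mm, theta rad).

        The tension-only laws are evaluated analytically at the state (so
        the gradient is exactly zero at tension onset); only the smooth
        geometric quantities (strains, gaps) are finite-differenced.
        """
        q = np.asarray(q, dtype=float)
        Q, steps = self._perturbed_states(q)
        t, theta = Q[:, :3], Q[:, 3:]
        R = rotvec_to_matrix(theta)
        R0 = rotvec_to_matrix(q[3:])

        out: dict[str, np.ndarray] = {}
        out["annulus"] = self.K6 * q

        dv_dq = np.zeros(6)
        dv_dq[2] = self.nucleus_area
        dv = self.nucleus_area * q[2]
        out["nucleus"] = self.series_bulk * dv / self.nucleus_volume * dv_dq

        eps_f0 = self._truss_strain(R0[None], q[None, :3], self.fib_pl, self.fib_pu, self.fib_L0)[0]
        f_fib = self.fib_EA * self.fib_L0 * _relu(eps_f0 + self.fib_pre)      # dU/deps per fibre
        eps_f = self._truss_strain(R, t, self.fib_pl, self.fib_pu, self.fib_L0)
        deps_f = (eps_f[0::2] - eps_f[1::2]) / (2.0 * steps[:, None])          # (6, nf)
        out["fibers"] = deps_f @ f_fib

        eps_l0 = self._truss_strain(R0[None], q[None, :3], self.lig_al, self.lig_au, self.lig_L0)[0]
        eps_eff0 = _relu(eps_l0 + self.lig_pre)
        stress0 = self.lig_E1 * np.minimum(eps_eff0, self.lig_ts) + self.lig_E2 * _relu(
            eps_eff0 - self.lig_ts
        )
        f_lig = self.lig_area * self.lig_L0 * stress0
        eps_l = self._truss_strain(R, t, self.lig_al, self.lig_au, self.lig_L0)
        deps_l = (eps_l[0::2] - eps_l[1::2]) / (2.0 * steps[:, None])
        out["ligaments"] = deps_l @ f_lig

        disp0 = (R0 @ self.fac_p.T).T + q[:3] - self.fac_p
        s0 = np.einsum("ni,ni->n", disp0, self.fac_n)
        f_fac = self.fac_k * (_relu(s0 - self.fac_g0) - _relu(-s0 - self.fac_g0))
        disp = np.einsum("bij,nj->bni", R, self.fac_p) + t[:, None, :] - self.fac_p
        s = np.einsum("bni,ni->bn", disp, self.fac_n)
        ds = (s[0::2] - s[1::2]) / (2.0 * steps[:, None])
        out["facets"] = ds @ f_fac
        return out

    def gradient_from_q(self, q: np.ndarray) -> np.ndarray:
        grads = self.constituent_gradients(q)
        return sum(grads.values())

    def volume_change_ratio(self, t_z: float) -> float:
        """Relative nucleus volume change for an axial relative displacement."""
        share = self.confinement_modulus / (self.nucleus_bulk + self.confinement_modulus)
        return float(share * self.nucleus_area * t_z / self.nucleus_volume)

    def ligament_forces(self, q: np.ndarray) -> dict[str, float]:
        """Tensile force (N) per ligament strand at a local state."""
        q = np.asarray(q, dtype=float)
        R = rotvec_to_matrix(q[3:])
        eps = self._truss_strain(R[None], q[None, :3], self.lig_al, self.lig_au, self.lig_L0)[0]
        eps_eff = _relu(eps + self.lig_pre)
        lo = np.minimum(eps_eff, self.lig_ts)
        hi = _relu(eps_eff - self.lig_ts)
        stress = self.lig_E1 * lo + self.lig_E2 * hi
        force = stress * self.lig_area
        out: dict[str, float] = {}
        for name, f in zip(self.lig_names, force):
            out[name] = out.get(name, 0.0) + float(f)
        return out

    def fiber_tensions(self, q: np.ndarray) -> np.ndarray:
        """Tensile force (N) per sampled fibre at a local state."""
        q = np.asarray(q, dtype=float)
        R = rotvec_to_matrix(q[3:])
        eps = self._truss_strain(R[None], q[None, :3], self.fib_pl, self.fib_pu, self.fib_L0)[0]
        return self.fib_EA * _relu(eps + self.fib_pre)


def _ellipse_inertia(a: float, b: float) -> tuple[float, float]:
    """(I_x, I_y) of a full ellipse with semi-axes a (x) and b (y)."""
    return np.pi / 4.0 * a * b**3, np.pi / 4.0 * b * a**3


def build_joint_model(
    geometry,
    card: MaterialCard,
    level: str,
    rest_geometry=None,
    extra_pre_strain: Mapping[str, float] | None = None,
) -> JointModel:
    """Condense one disc level of a geometry + material card.

    ``rest_geometry`` supplies the stress-free lengths of fibres and
    ligaments (defaults to ``geometry`` itself); passing the healthy
    geometry while building a height-reduced degenerated one slackens all
    trans-disc soft tissues, which is the mechanical signature of disc
    height loss.  ``extra_pre_strain`` adds (nonpositive) strain offsets per
    ligament name.
    """
    rest_geometry = rest_geometry if rest_geometry is not None else geometry
    extra_pre = dict(extra_pre_strain or {})
    disc = geometry.discs[level]
    rest_disc = rest_geometry.discs[level]
    cfg = geometry.config
    h = disc.height
    a, b = disc.annulus_outer_radius_ml, disc.annulus_outer_radius_ap
    f = disc.nucleus_area_fraction
    A_total, A_n, A_a = disc.area, disc.nucleus_area, disc.annulus_area
    Ix_o, Iy_o = _ellipse_inertia(a, b)
    Ix_a, Iy_a = Ix_o * (1.0 - f**2), Iy_o * (1.0 - f**2)
    Ix_n, Iy_n = Ix_o * f**2, Iy_o * f**2
    J_a, J_n = Ix_a + Iy_a, Ix_n + Iy_n

    E, nu = card.annulus.E, card.annulus.nu
    G = E / (2.0 * (1.0 + nu))
    # interlamellar sliding: the layered matrix transmits only a fraction of
    # the solid-section shear (in-plane shear and torsion)
    kappa = float(cfg["disc"].get("annulus_shear_correction", 1.0))
    M_conf = E * (1.0 - nu) / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu_n = card.nucleus.shear_modulus
    E_n_bend = 3.0 * mu_n  # incompressible-limit Young modulus for bending terms

    K6 = np.array(
        [
            kappa * G * A_a / h + mu_n * A_n / h,
            kappa * G * A_a / h + mu_n * A_n / h,
            M_conf * A_a / h,
            M_conf * Ix_a / h + E_n_bend * Ix_n / h,
            M_conf * Iy_a / h + E_n_bend * Iy_n / h,
            kappa * G * J_a / h + mu_n * J_n / h,
        ]
    )

    # cavity confinement of the nucleus by the annulus wall: thick-walled
    # Lame compliance of the ground substance (the tension-only fibres are
    # near-slack in the compression-dominated states where the cavity model
    # matters, so they do not stiffen the wall here)
    fib_cfg = cfg["fibers"]
    vf = float(fib_cfg["volume_fraction"])
    r_out = float(np.sqrt(a * b))
    r_n = r_out * np.sqrt(f)
    lame_ratio = (r_out**2 + r_n**2) / (r_out**2 - r_n**2)
    c_b = E / (2.0 * (lame_ratio + nu))

    if isinstance(card.nucleus, MooneyRivlinNucleus):
        K_n = float(cfg["disc"]["nucleus_penalty_bulk_factor"]) * E
    else:
        K_n = card.nucleus.bulk_modulus
    V0 = A_n * h

    # fibre trusses from the sampled layers
    V_annulus = A_a * h
    layers = geometry.fiber_layers[level]
    rest_layers = rest_geometry.fiber_layers[level]
    n_layers = len(layers)
    pl, pu, L0, EA, idx = [], [], [], [], []
    for spec, rest_spec in zip(layers, rest_layers):
        alpha = np.radians(spec.orientation_deg)
        n_fib = len(spec.sample_points)
        V_layer = vf * V_annulus / n_layers
        for (pos, d), (rpos, rd) in zip(spec.sample_points, rest_spec.sample_points):
            half = (h / 2.0) / d[2]
            p_lo = pos - d * half
            p_up = pos + d * half
            rest_len = rest_disc.height / rd[2]
            area = V_layer / n_fib / rest_len
            pl.append(p_lo)
            pu.append(p_up)
            L0.append(rest_len)
            EA.append(card.fiber_layer_E[spec.layer_index - 1] * area)
            idx.append(spec.layer_index)
    fib_pl, fib_pu = np.asarray(pl), np.asarray(pu)
    fib_L0, fib_EA = np.asarray(L0), np.asarray(EA)
    fib_layer = np.asarray(idx)

    # ligaments of this level, in disc-local coordinates
    A_w = disc.axes
    c_w = disc.centroid
    names, al, au, L0l, area, E1, E2, ts, pre = [], [], [], [], [], [], [], [], []
    ligs = [l for l in geometry.ligaments if l.level == level]
    rest_ligs = [l for l in rest_geometry.ligaments if l.level == level]
    for lig, rest in zip(ligs, rest_ligs):
        law = card.ligaments[lig.name]
        names.append(lig.name)
        al.append(A_w.T @ (lig.origin - c_w))
        au.append(A_w.T @ (lig.insertion - c_w))
        L0l.append(rest.rest_length)
        area.append(lig.cross_section)
        E1.append(law.E1)
        E2.append(law.E2)
        ts.append(law.transition_strain)
        pre.append(lig.pre_strain + extra_pre.get(lig.name, 0.0))

    fac_p, fac_n, fac_g0, fac_k = [], [], [], []
    for fac in (x for x in geometry.facets if x.level == level):
        fac_p.append(A_w.T @ (fac.contact_point - c_w))
        fac_n.append(A_w.T @ fac.normal)
        fac_g0.append(fac.gap)
        fac_k.append(fac.stiffness)

    return JointModel(
        level=level,
        height=h,
        center_world=c_w,
        axes_world=A_w,
        K6=K6,
        nucleus_area=A_n,
        nucleus_volume=V0,
        confinement_modulus=c_b,
        nucleus_bulk=K_n,
        fib_pl=fib_pl,
        fib_pu=fib_pu,
        fib_L0=fib_L0,
        fib_EA=fib_EA,
        fib_pre=np.zeros_like(fib_L0),
        fib_layer=fib_layer,
        lig_names=tuple(names),
        lig_al=np.asarray(al),
        lig_au=np.asarray(au),
        lig_L0=np.asarray(L0l),
        lig_area=np.asarray(area),
        lig_E1=np.asarray(E1),
        lig_E2=np.asarray(E2),
        lig_ts=np.asarray(ts),
        lig_pre=np.asarray(pre),
        fac_p=np.asarray(fac_p),
        fac_n=np.asarray(fac_n),
        fac_g0=np.asarray(fac_g0),
        fac_k=np.asarray(fac_k),
    )


@dataclass
class ResolvedLoad:
    """Loads resolved to world-frame primitives the chain can integrate.

    ``moments``: (vertebra label, moment vector N*mm world).
    ``slips``: (vertebra label, force N, attachment point world, anchor world).
    ``preload``: follower compression magnitude, N.
    """

    preload: float = 0.0
    preload_type: str = "follower"
    moments: tuple = ()
    slips: tuple = ()


class ChainModel:
    """The assembled L?-sacrum chain with batched energy evaluation."""

    def __init__(
        self,
        geometry,
        card_map: Mapping[str, MaterialCard],
        rest_geometry=None,
        extra_pre_strain: Mapping[str, Mapping[str, float]] | None = None,
    ):
        self.geometry = geometry
        self.joint_levels: tuple[str, ...] = tuple(geometry.joints)
        extra = extra_pre_strain or {}
        self.joints = [
            build_joint_model(
                geometry,
                card_map[level],
                level,
                rest_geometry=rest_geometry,
                extra_pre_strain=extra.get(level),
            )
            for level in self.joint_levels
        ]
        # vertebra labels bottom-up (upper vertebra of each joint)
        self.vertebrae = tuple(level.split("-")[0] for level in self.joint_levels)
        self.n_joints = len(self.joints)
        self.ndof = 6 * self.n_joints
        self.centroids = np.stack(
            [geometry.frames["S"].origin]
            + [geometry.frames[v].origin for v in self.vertebrae]
        )
        # neutral link lengths, subtracted from the follower potential so the
        # energy is zero at the neutral state (conditioning of the FD solver)
        self._link_rest = np.linalg.norm(np.diff(self.centroids, axis=0), axis=1)

    # -- kinematics -------------------------------------------------------
    def poses(self, q: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        """World affine maps (R, d) per vertebra bottom-up for (…, J, 6) q."""
        q = np.asarray(q, dtype=float)
        batch = q.shape[:-2]
        R_acc = np.broadcast_to(np.eye(3), batch + (3, 3)).copy()
        d_acc = np.zeros(batch + (3,))
        out = []
        for k, joint in enumerate(self.joints):
            A, c = joint.axes_world, joint.center_world
            t_l, th_l = q[..., k, :3], q[..., k, 3:]
            R_l = rotvec_to_matrix(th_l)
            R_w = A @ R_l @ A.T
            t_w = t_l @ A.T
            # local map: x -> R_w (x - c) + c + t_w ; compose below pose
            R_new = R_acc @ R_w
            d_new = np.einsum("...ij,...j->...i", R_acc, c + t_w - np.einsum("...ij,j->...i", R_w, c)) + d_acc
            out.append((R_new, d_new))
            R_acc, d_acc = R_new, d_new
        return out

    def internal_energy(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        total = 0.0
        for k, joint in enumerate(self.joints):
            total = total + joint.energy_from_q(q[..., k, :])
        return total

    def external_potential(self, q: np.ndarray, load: ResolvedLoad, scale: float = 1.0) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        batch = q.shape[:-2]
        U = np.zeros(batch)
        poses = self.poses(q)
        pose_of = dict(zip(self.vertebrae, poses))

        if load.preload:
            pts = [np.broadcast_to(self.centroids[0], batch + (3,))]
            for i, v in enumerate(self.vertebrae):
                R, d = pose_of[v]
                pts.append(np.einsum("...ij,j->...i", R, self.centroids[i + 1]) + d)
            if load.preload_type == "follower":
                # compressive pairs along the deformed inter-centroid lines
                for rest, lo, hi in zip(self._link_rest, pts[:-1], pts[1:]):
                    U = U + scale * load.preload * (np.linalg.norm(hi - lo, axis=-1) - rest)
            else:
                # fixed-direction (vertical) load at the top vertebra
                U = U + scale * load.preload * (pts[-1][..., 2] - self.centroids[-1, 2])

        for label, mvec in load.moments:
            R, _ = pose_of[label]
            theta = matrix_to_rotvec(R)
            U = U - scale * np.einsum("...i,i->...", theta, np.asarray(mvec, dtype=float))

        for label, force, attach, anchor in load.slips:
            attach = np.asarray(attach, dtype=float)
            anchor = np.asarray(anchor, dtype=float)
            R, d = pose_of[label]
            p = np.einsum("...ij,j->...i", R, attach) + d
            rest = np.linalg.norm(attach - anchor)
            U = U + scale * force * (np.linalg.norm(p - anchor, axis=-1) - rest)
        return U

    def total_potential(self, q: np.ndarray, load: ResolvedLoad, scale: float = 1.0) -> np.ndarray:
        return self.internal_energy(q) + self.external_potential(q, load, scale)
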