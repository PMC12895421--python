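# lrfit

Symmetry-adapted spherical-tensor expansions of long-range intermolecular
interactions, with staged nonlinear fitting of the expansion coefficients
to scattered ab initio interaction energies.

## The problem

At large center-of-mass separation R, the interaction energy of two rigid
molecules separates into electrostatic, induction and dispersion
contributions, each an inverse-power series in R whose angular structure
is fixed by the molecules' multipole moments, polarizabilities and
dispersion coefficients.  In the spherical-tensor form,

    E(R, Ω_A, Ω_B) = E_asym
        + Σ_{t,u}  Q_t^A Q_u^B T_{t,u}
        − ½ Σ  α^A_{t;t'} Q_u^B Q_{u'}^B T_{t,u} T_{t',u'}   (+ A↔B)
        − Σ    D_{t,u;t',u'} T_{t,u} T_{t',u'}

where t = (l, m, c/s) are Stone's real component labels, T_{t,u} is the
purely geometric interaction tensor (∝ R^−(l_t+l_u+1), built from a Wigner
3-j coupling along the dimer axis and a Wigner rotation per monomer), and
an order-n term varies as R^−n.  The spherical form needs only 2n²
electrostatic coefficients through order n (72 at order 6, 450 at 15)
versus 3^n − 1 Cartesian ones (728 at order 6, ~14.3 million at 15).

Each monomer's point group prunes the coefficient lists: only the totally
symmetric combinations of each rank survive (a homonuclear diatomic keeps
the quadrupole and hexadecapole but no dipole; a tetrahedral molecule
first contributes at the octupole; an icosahedral one at rank 6).  `lrfit`
computes these surviving combinations for every molecular point group by
numeric group-averaged projection, assembles the complete symmetry-adapted
term list up to 15th order, and determines the coefficients — including
the asymptotic energy E_asym — by order-by-order Levenberg–Marquardt
least squares on scattered energies, honoring exact constraints for
identical or mirror-image (chiral partner) monomers and for any
coefficients fixed to known values.  It is aimed at building potential
energy surfaces with correct asymptotics for spectroscopy and cold
collision studies.

## Worked example

Fit a synthetic charged-linear + centrosymmetric-linear system (the
CF⁺–H₂ symmetry class) and watch the staged statistics:

```sh
lrfit synth --group-a Cinfv --charge-a 1 --group-b Dinfh \
      --n 200 --elec 5 --ind 4 --disp 0 --seed 3 --out s.dat
lrfit fit --group-a Cinfv --charge-a 1 --group-b Dinfh \
      --max-order 5 s.dat --coefficients fit.json
```

prints (energies in hartree):

```
 stage  elec  ind  disp  n_free        RMSE       R2  converged   Q_B[20]  Q_A[10]    Q_B[40]   Q_A[20]
     1     3    0     0       2 2.67484e-07 0.999501       True -0.637437      NaN        NaN       NaN
     2     4    4     0       3 1.02814e-08 0.999999       True -0.638873 0.208839        NaN       NaN
     3     5    5     0       7 1.60356e-20        1       True -0.638916 0.209049 -0.0354856 -0.113162

E_asym = 0.0002040919121 hartree
final RMSE = 1.60356e-20 hartree, R^2 = 1
outliers flagged: 0
```

Each row introduces the next inverse-power order (electrostatics opens at
the charge–quadrupole R⁻³ term, induction at R⁻⁴); the RMSE falls and the
leading coefficients stabilize — here to the exact generating values, the
partner quadrupole Q_B[20] = −0.6389 a.u. among them, because the known
charge of molecule A pins the whole cascade of coefficient products.  The
same workflow is available as a library:

```python
from lrfit import MoleculeSpec, SystemSpec, LongRangeModel
from lrfit.data_io import read_dataset

sysspec = SystemSpec(MoleculeSpec("CF+", "Cinfv", charge=1.0),
                     MoleculeSpec("H2", "Dinfh"))
data = read_dataset("s.dat", sys=sysspec)
res = LongRangeModel(data, sysspec).fit()
print(res.summary())
```

`lrfit terms` prints the symmetry-allowed term tables per order,
`lrfit filter` applies the minimal inter-fragment atom-pair distance
(LeRoy) admission rule for strongly anisotropic molecules, and
`lrfit export` writes a fitted model as a machine-readable term file plus
a self-contained Fortran subroutine for use in scattering codes.

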