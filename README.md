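# coreadc

Reduced-cost density-fitted CVS-ADC(2) calculations of K-edge (1s core
level) excitation energies and oscillator strengths for small
closed-shell molecules.

X-ray absorption near-edge spectra probe 1s -> valence/Rydberg
excitations at element-specific energies (C ~290 eV, N ~400 eV,
O ~535 eV).  The second-order algebraic-diagrammatic construction with
core-valence separation, CVS-ADC(2), is one of the best
accuracy/cost trade-offs for such states, but its fifth-power scaling
limits routine use.  This package implements the method together with a
two-stage compression that attacks the two dimensions dominating the
cost:

* **NAF** - natural auxiliary functions: the density-fitting three-center
  factor `J` (with `(pq|rs) = sum_Q J^Q_pq J^Q_rs`) is compressed by
  diagonalizing `W = sum_pq J_pq J_pq^T`; auxiliary directions with
  singular value below `eps_NAF` are dropped.
* **VNO** - state-specific frozen virtual natural orbitals: for each
  excited state a state-averaged virtual-virtual density
  `D = (D_MP2 + D_CVS-CIS(D))/2` is diagonalized and virtuals with
  occupation below `eps_VNO` are dropped, followed by semicanonicalization
  and a second NAF truncation in the reduced space.

The CVS-ADC(2) equations are solved in folded form: an omega-dependent
effective Jacobian acts in the singles space only,

    sigma(r, w) = sigma_CIS(r) + sigma_GS(r) + sigma_D(r, w),
    w = <r|sigma(r, w)>,

with the doubles coefficients (denominators containing `w`) built on the
fly and never stored.  A modified state-specific Davidson iteration with
DIIS acceleration solves the nonlinear eigenproblem from CVS-CIS guesses.
Oscillator strengths are computed in the dipole-length gauge from a
correlated transition density.  Everything runs on a self-contained
McMurchie-Davidson integral engine and an RHF/DIIS reference; defaults
are `eps_NAF = 0.1` au and `eps_VNO = 7.5e-5`.

See `docs/methods.md` for the working equations, the auxiliary-basis
construction, the exact term content of the transition density, and the
validation methodology (including the full-CI perturbation-order test
that pins the second-order secular matrix).

## Worked example

Canonical versus reduced-cost O K-edge of water (built-in fixture
geometry, split-valence double-zeta basis):

```sh
coreadc run --fixture h2o --cvs "O 1s" --n-states 3 --mode canonical \
            --no-cache -o canonical.json
coreadc run --fixture h2o --cvs "O 1s" --n-states 3 --mode reduced \
            --no-cache -o reduced.json
coreadc stats canonical.json reduced.json
```

The two runs print

```
# h2o  O 1s K-edge  basis=6-31g  mode=canonical
state   omega/eV        f    VNO%    NAF%  conv
    1     538.34   0.0185   100.0   100.0   yes
    2     540.66   0.0410   100.0   100.0   yes
    3     560.79   0.1212   100.0   100.0   yes

# h2o  O 1s K-edge  basis=6-31g  mode=reduced
state   omega/eV        f    VNO%    NAF%  conv
    1     538.34   0.0185   100.0    29.4   yes
    2     540.65   0.0410   100.0    29.4   yes
    3     560.80   0.1212   100.0    29.4   yes
```

Columns: excitation energy (eV), oscillator strength, and the
percentages of virtual natural orbitals and of auxiliary functions
retained by the compression.  Here the NAF step keeps 29% of the fitting
basis while the small virtual space of this basis survives the VNO
cutoff intact; the energies agree to a few meV.  The `stats` subcommand
then reports the error measures between the two structured outputs
(mean/maximum absolute deviation and standard deviation of the energies;
mean/maximum relative deviation of the oscillator strengths for
transitions with f > 0.015):

```
{
 "n_states": 3,
 "mae_ev": 0.004872803386547275,
 "max_ev": 0.008391355262347133,
 ...
}
```

The same pipeline is available as a library:

```python
from coreadc import RunConfig, run_calculation, error_statistics
canonical = run_calculation(RunConfig(geometry="h2o", cvs="O 1s",
                                      mode="canonical"))
reduced = run_calculation(RunConfig(geometry="h2o", cvs="O 1s",
                                    mode="reduced"))
print(error_statistics(canonical, reduced))
```

Geometries can also be given as standard XYZ files (`--xyz path`), and a
YAML config file can replace the flags (`--config run.yaml`; flags
override file keys).

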