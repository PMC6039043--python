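"""Physical constants used throughout the package (SI units, CODATA via scipy)."""

from scipy.constants import c as C  # vacuum speed of light, 299792458 m/s (exact)
from scipy.constants import epsilon_0 as EPS0
from scipy.constants import mu_0 as MU0

__all__ = ["C", "EPS0", "MU0"]
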