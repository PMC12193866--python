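"""Array layouts shared by the object model and the numba kernels.

The transfer-function manager, volumes and octree are flattened to plain
ndarrays before entering the compiled kernels; these constants pin the column
meanings on both sides.
"""

# coefficient-vector row (one row per TF control point / interval / label)
NC = 15
C_OP = 0          # opacity scale (maps to sigma_t magnitude)
C_A = 1           # 1:4  surface albedo RGB
C_S = 4           # 4:7  volumetric (spherical scattering) albedo RGB
C_LE = 7          # 7:10 emission radiance RGB
C_ROUGH = 10
C_METAL = 11
C_G = 12          # phase asymmetry
C_KIND = 13       # material kind code
C_SURF = 14       # fixed surface probability Pfs; -1 = gradient-driven

FORM_CODES = {"CCTF": 0, "CPCTF": 1, "CDPTF": 2, "MPCTF": 3, "MDPTF": 4}
KIND_CODES = {"diffuse": 0, "metal": 1, "dielectric": 2, "emissive": 3,
              "highlight": 4}
MODE_CODES = {"multiply": 0, "priority": 1}
CHAN_CODES = {"single": 0, "multi": 1}

# optical-properties output row written by the manager-evaluation kernel
NOUT = 32
O_SIGT = 0        # extinction magnitude (channel-uniform, per world unit)
O_SIGA = 1        # 1:4  absorption per channel
O_SIGS = 4        # 4:7  total scattering per channel
O_A = 7           # 7:10 surface albedo
O_S = 10          # 10:13 volumetric albedo
O_LE = 13         # 13:16 emission radiance
O_PFS = 16        # surface-scattering particle probability
O_ROUGH = 17
O_METAL = 18
O_G = 19          # phase asymmetry
O_GRAD = 20       # 20:23 gradient of the primary volume (per world unit)
O_KIND = 23
O_W = 24          # single-channel-mode scattering fraction sigma_s/sigma_t
O_OP = 25         # combined opacity scale before density scaling
O_SVS = 26        # 26:29 volume-scattering coefficient per channel
O_SFS = 29        # 29:32 surface-scattering coefficient per channel

# per-proxy metadata row
NVM = 12
VM_USED = 0
VM_DISCRETE = 1
VM_DIMS = 2       # 2:5
VM_SPACING = 5    # 5:8
VM_ORIGIN = 8     # 8:11
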