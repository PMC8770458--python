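"""Per-mitochondrion 3-D morphometry on a synthetic label volume.

For every labelled object: spatial subtype (SSM/IFM/PNM), exact voxel
volume, iso-surface mesh surface area, SA/Vol, oval/irregular shape class
and any tubular projections.  Printed means can be compared directly with
the generator's ground truth.
"""

import numpy as np

from mitomorph.morphometry import morphometry_dataframe, morphometry_table
from mitomorph.synthetic import VolumeParams, generate_cardiomyocyte_volume

# wild-type study conditions; generation plus measurement takes ~2 minutes
params = VolumeParams(shape_zyx=(48, 640, 640), seed=2)
volume, truth = generate_cardiomyocyte_volume(params)
records = morphometry_table(volume)
df = morphometry_dataframe(records)

print(f"{len(df)} mitochondria measured")
for subtype, grp in df.groupby("subtype"):
    true_vol = np.mean(
        [o.voxel_volume_nm3 for o in truth.objects.values() if o.subtype == subtype]
    )
    print(
        f"{subtype}: n={len(grp):3d}  "
        f"Vol {grp.volume_nm3.mean():.3g} nm^3 (truth {true_vol:.3g})  "
        f"SA {grp.surface_area_nm2.mean():.3g} nm^2  "
        f"SA/Vol {grp.sa_over_vol_per_nm.mean():.2e} /nm  "
        f"oval {100 * (grp.shape_class == 'oval').mean():.0f}%  "
        f"with projection {100 * grp.has_projection.mean():.0f}%"
    )
# Volumes are exact voxel counts; surface areas come from a marching-cubes
# mesh in physical coordinates and sit within a few percent of the
# generator's analytic areas.
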