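"""Read single intensities and whole time series from compressed data.

No other voxel is decompressed: each read is one offset computation, one
bounded two-word bit read, and one addition.
"""

import numpy as np

from ctpcodec import (
    PhantomSpec,
    compress,
    generate_phantom,
    read_timeseries,
    read_voxel,
)

img, labels = generate_phantom(PhantomSpec(shape=(4, 64, 64), seed=1))
cimg = compress(img)

# pick one vessel voxel and one brain-tissue voxel from the label map
vz, vy, vx = (int(i[0]) for i in np.nonzero(labels == 4))
bz, by, bx = (int(i[0]) for i in np.nonzero(labels == 2))

vessel = read_timeseries(cimg, vz, vy, vx)
brain = read_timeseries(cimg, bz, by, bx)
print(f"vessel voxel ({vz},{vy},{vx}): range {vessel.min()}..{vessel.max()} HU "
      f"-> {int(cimg.B[cimg.voxel_index(vz, vy, vx)])} bits/delta")
print(f"brain voxel  ({bz},{by},{bx}): range {brain.min()}..{brain.max()} HU "
      f"-> {int(cimg.B[cimg.voxel_index(bz, by, bx)])} bits/delta")

t_peak = int(np.argmax(vessel))
value = read_voxel(cimg, vz, vy, vx, t_peak)
print(f"single read at bolus peak t={t_peak}: {value} HU "
      f"(matches the uncompressed value: {value == img.data[t_peak, vz, vy, vx]})")
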