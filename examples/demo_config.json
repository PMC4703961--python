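{
  "seed": 1,
  "demo_scenes": 1,
  "demo_image_shape": [48, 48],
  "demo_cells": 3,
  "demo_cell_radius": [5.0, 7.0],
  "design": {
    "samples": ["S1"],
    "preparations": ["fresh", "flash_frozen", "dmso_frozen"],
    "treatments": ["control", "paclitaxel", "combo"],
    "timepoints_hr": [24, 48, 72],
    "organoids_per_group": 6,
    "cells_per_organoid": 10,
    "effects": {
      "S1|fresh|paclitaxel|48": [-0.5, -0.5, 0.5],
      "S1|fresh|paclitaxel|72": [-1, -1, 1],
      "S1|fresh|combo|24": [-0.5, -0.5, 0.5],
      "S1|fresh|combo|48": [-1, -1, 1],
      "S1|fresh|combo|72": [-1, -1, 1],
      "S1|dmso_frozen|paclitaxel|72": [-1, -1, 1],
      "S1|dmso_frozen|combo|48": [-0.5, -0.5, 0.5],
      "S1|dmso_frozen|combo|72": [-1, -1, 1],
      "S1|flash_frozen|combo|72": [-1, -1, 1]
    },
    "seed": 1
  }
}
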