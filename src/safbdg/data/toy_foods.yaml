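# Illustrative QFFQ-style food list (synthetic; not a reconstruction of any
# survey instrument). Covers every scored food family and all nine FAO
# dietary-diversity groups. Starchy items carry the published food-guide
# unit weights; kj_per_g are toy energy densities for the generator.
schema_version: 1
items:
  maize_porridge_soft:    {dds_group: 1, families: [starchy], starchy_unit_g: 125, kj_per_g: 2.4}
  maize_porridge_stiff:   {dds_group: 1, families: [starchy], starchy_unit_g: 60,  kj_per_g: 5.0}
  maize_porridge_crumbly: {dds_group: 1, families: [starchy], starchy_unit_g: 45,  kj_per_g: 6.0}
  brown_bread:            {dds_group: 1, families: [starchy], starchy_unit_g: 35,  kj_per_g: 10.2}
  white_bread:            {dds_group: 1, families: [starchy], starchy_unit_g: 35,  kj_per_g: 10.5}
  cooked_rice:            {dds_group: 1, families: [starchy], starchy_unit_g: 65,  kj_per_g: 5.5}
  cooked_pasta:           {dds_group: 1, families: [starchy], starchy_unit_g: 75,  kj_per_g: 5.9}
  samp:                   {dds_group: 1, families: [starchy], starchy_unit_g: 75,  kj_per_g: 5.0}
  potato:                 {dds_group: 1, families: [starchy], starchy_unit_g: 100, kj_per_g: 3.2}
  sweet_potato:           {dds_group: 1, families: [starchy], starchy_unit_g: 100, kj_per_g: 3.6}
  breakfast_cereal:       {dds_group: 1, families: [starchy], starchy_unit_g: 25,  kj_per_g: 15.0}
  chicken_cooked:         {dds_group: 2, families: [fish_chicken_leanmeat], kj_per_g: 7.0}
  hake_fish:              {dds_group: 2, families: [fish_chicken_leanmeat], kj_per_g: 4.7}
  tinned_pilchards:       {dds_group: 2, families: [fish_chicken_leanmeat], kj_per_g: 6.0}
  beef_lean:              {dds_group: 2, families: [fish_chicken_leanmeat], kj_per_g: 8.5}
  processed_meat:         {dds_group: 2, families: [], kj_per_g: 11.0}
  mutton_fatty:           {dds_group: 2, families: [], kj_per_g: 13.0}
  milk_full_cream:        {dds_group: 3, families: [dairy_liquid], kj_per_g: 2.7}
  maas:                   {dds_group: 3, families: [dairy_liquid], kj_per_g: 2.6}
  yoghurt:                {dds_group: 3, families: [dairy_liquid], kj_per_g: 3.7}
  cheddar_cheese:         {dds_group: 3, families: [hard_cheese], kj_per_g: 17.0}
  egg:                    {dds_group: 4, families: [egg], kj_per_g: 6.5}
  carrot:                 {dds_group: 5, families: [fruit_veg], kj_per_g: 1.7}
  butternut:              {dds_group: 5, families: [fruit_veg], kj_per_g: 1.5}
  spinach_morogo:         {dds_group: 5, families: [fruit_veg], kj_per_g: 1.0}
  mango:                  {dds_group: 5, families: [fruit_veg], kj_per_g: 2.5}
  pawpaw:                 {dds_group: 5, families: [fruit_veg], kj_per_g: 1.6}
  dry_beans_cooked:       {dds_group: 6, families: [legume], kj_per_g: 4.0}
  lentils_cooked:         {dds_group: 6, families: [legume], kj_per_g: 4.2}
  split_peas_cooked:      {dds_group: 6, families: [legume], kj_per_g: 4.0}
  soya_mince:             {dds_group: 6, families: [legume], kj_per_g: 4.5}
  cabbage:                {dds_group: 7, families: [fruit_veg], kj_per_g: 1.0}
  tomato:                 {dds_group: 7, families: [fruit_veg], kj_per_g: 0.8}
  onion:                  {dds_group: 7, families: [fruit_veg], kj_per_g: 1.6}
  green_beans:            {dds_group: 7, families: [fruit_veg], kj_per_g: 1.3}
  apple:                  {dds_group: 8, families: [fruit_veg], kj_per_g: 2.2}
  banana:                 {dds_group: 8, families: [fruit_veg], kj_per_g: 3.8}
  orange:                 {dds_group: 8, families: [fruit_veg], kj_per_g: 1.9}
  sunflower_oil:          {dds_group: 9, families: [], kj_per_g: 37.0}
  margarine:              {dds_group: 9, families: [], kj_per_g: 30.0}
  mayonnaise:             {dds_group: 9, families: [], kj_per_g: 28.0}
  peanut_butter:          {dds_group: 9, families: [], kj_per_g: 26.0}
  white_sugar:            {families: [], kj_per_g: 17.0}
  carbonated_drink:       {families: [], kj_per_g: 1.8}
  sweets:                 {families: [], kj_per_g: 16.0}
  salty_snacks:           {families: [], kj_per_g: 20.0}
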