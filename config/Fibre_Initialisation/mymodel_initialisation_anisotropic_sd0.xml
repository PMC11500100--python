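<?xml version='1.0' encoding='utf-8'?>
<simulation>
  <domain x_min="-400.0" x_max="400.0" y_min="-400.0" y_max="400.0" voxel_size="30.0" />
  <overall dt_mechanics="0.1" dt_diffusion="0.05" t_max="1.0" output_interval="1.0" />
  <options rng_seed="0" adjacency_rings="2" />
  <substrate diffusion_coefficient="800.0" decay_rate="0.02" />
  <cell_definitions>
    <cell_definition name="default_fibre" initial_count="2000">
      <custom_data>
        <fibre_length>75.0</fibre_length>
        <length_normdist_sd>0.0</length_normdist_sd>
        <fibre_radius>2.0</fibre_radius>
        <radius_normdist_sd>0.0</radius_normdist_sd>
        <anisotropic_fibres>1</anisotropic_fibres>
        <fibre_angle>0.2</fibre_angle>
        <angle_normdist_sd>0.0</angle_normdist_sd>
        <fibre_sticky>1.0</fibre_sticky>
      </custom_data>
    </cell_definition>
  </cell_definitions>
</simulation>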