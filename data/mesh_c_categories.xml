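<?xml version="1.0" encoding="UTF-8"?>
<DescriptorRecordSet LanguageCode="eng">
  <DescriptorRecord DescriptorClass="1">
    <DescriptorName><String>Infections</String></DescriptorName>
    <TreeNumberList><TreeNumber>C01</TreeNumber></TreeNumberList>
  </DescriptorRecord>
  <DescriptorRecord DescriptorClass="1">
    <DescriptorName><String>Neoplasms</String></DescriptorName>
    <TreeNumberList><TreeNumber>C04</TreeNumber></TreeNumberList>
  </DescriptorRecord>
  <DescriptorRecord DescriptorClass="1">
    <DescriptorName><String>Musculoskeletal Diseases</String></DescriptorName>
    <TreeNumberList><TreeNumber>C05</TreeNumber></TreeNumberList>
  </DescriptorRecord>
  <DescriptorRecord DescriptorClass="1">
    <DescriptorName><String>Digestive System Diseases</String></DescriptorName>
    <TreeNumberList><TreeNumber>C06</TreeNumber></TreeNumberList>
  </DescriptorRecord>
  <DescriptorRecord DescriptorClass="1">
    <DescriptorName><String>Stomatognathic Diseases</String></DescriptorName>
    <TreeNumberList><TreeNumber>C07</TreeNumber></TreeNumberList>
  </DescriptorRecord>
  <DescriptorRecord DescriptorClass="1">
    <DescriptorName><String>Respiratory Tract Diseases</String></DescriptorName>
    <TreeNumberList><TreeNumber>C08</TreeNumber></TreeNumberList>
  </DescriptorRecord>
  <DescriptorRecord DescriptorClass="1">
    <DescriptorName><String>Otorhinolaryngologic Diseases</String></DescriptorName>
    <TreeNumberList><TreeNumber>C09</TreeNumber></TreeNumberList>
  </DescriptorRecord>
  <DescriptorRecord DescriptorClass="1">
    <DescriptorName><String>Nervous System Diseases</String></DescriptorName>
    <TreeNumberList><TreeNumber>C10</TreeNumber></TreeNumberList>
  </DescriptorRecord>
  <DescriptorRecord DescriptorClass="1">
    <DescriptorName><String>Eye Diseases</String></DescriptorName>
    <TreeNumberList><TreeNumber>C11</TreeNumber></TreeNumberList>
  </DescriptorRecord>
  <DescriptorRecord DescriptorClass="1">
    <DescriptorName><String>Urogenital Diseases</String></DescriptorName>
    <TreeNumberList><TreeNumber>C12</TreeNumber></TreeNumberList>
  </DescriptorRecord>
  <DescriptorRecord DescriptorClass="1">
    <DescriptorName><String>Cardiovascular Diseases</String></DescriptorName>
    <TreeNumberList><TreeNumber>C14</TreeNumber></TreeNumberList>
  </DescriptorRecord>
  <DescriptorRecord DescriptorClass="1">
    <DescriptorName><String>Hemic and Lymphatic Diseases</String></DescriptorName>
    <TreeNumberList><TreeNumber>C15</TreeNumber></TreeNumberList>
  </DescriptorRecord>
  <DescriptorRecord DescriptorClass="1">
    <DescriptorName><String>Congenital, Hereditary, and Neonatal Diseases and Abnormalities</String></DescriptorName>
    <TreeNumberList><TreeNumber>C16</TreeNumber></TreeNumberList>
  </DescriptorRecord>
  <DescriptorRecord DescriptorClass="1">
    <DescriptorName><String>Skin and Connective Tissue Diseases</String></DescriptorName>
    <TreeNumberList><TreeNumber>C17</TreeNumber></TreeNumberList>
  </DescriptorRecord>
  <DescriptorRecord DescriptorClass="1">
    <DescriptorName><String>Nutritional and Metabolic Diseases</String></DescriptorName>
    <TreeNumberList><TreeNumber>C18</TreeNumber></TreeNumberList>
  </DescriptorRecord>
  <DescriptorRecord DescriptorClass="1">
    <DescriptorName><String>Endocrine System Diseases</String></DescriptorName>
    <TreeNumberList><TreeNumber>C19</TreeNumber></TreeNumberList>
  </DescriptorRecord>
  <DescriptorRecord DescriptorClass="1">
    <DescriptorName><String>Immune System Diseases</String></DescriptorName>
    <TreeNumberList><TreeNumber>C20</TreeNumber></TreeNumberList>
  </DescriptorRecord>
  <DescriptorRecord DescriptorClass="1">
    <DescriptorName><String>Disorders of Environmental Origin</String></DescriptorName>
    <TreeNumberList><TreeNumber>C21</TreeNumber></TreeNumberList>
  </DescriptorRecord>
  <DescriptorRecord DescriptorClass="1">
    <DescriptorName><String>Animal Diseases</String></DescriptorName>
    <TreeNumberList><TreeNumber>C22</TreeNumber></TreeNumberList>
  </DescriptorRecord>
  <DescriptorRecord DescriptorClass="1">
    <DescriptorName><String>Pathological Conditions, Signs and Symptoms</String></DescriptorName>
    <TreeNumberList><TreeNumber>C23</TreeNumber></TreeNumberList>
  </DescriptorRecord>
  <DescriptorRecord DescriptorClass="1">
    <DescriptorName><String>Occupational Diseases</String></DescriptorName>
    <TreeNumberList><TreeNumber>C24</TreeNumber></TreeNumberList>
  </DescriptorRecord>
  <DescriptorRecord DescriptorClass="1">
    <DescriptorName><String>Chemically-Induced Disorders</String></DescriptorName>
    <TreeNumberList><TreeNumber>C25</TreeNumber></TreeNumberList>
  </DescriptorRecord>
  <DescriptorRecord DescriptorClass="1">
    <DescriptorName><String>Wounds and Injuries</String></DescriptorName>
    <TreeNumberList><TreeNumber>C26</TreeNumber></TreeNumberList>
  </DescriptorRecord>
</DescriptorRecordSet>
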