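<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           xmlns:po="urn:x-pathterm:observation:1"
           targetNamespace="urn:x-pathterm:observation:1"
           elementFormDefault="qualified">

  <xs:complexType name="CodedConcept">
    <xs:attribute name="code" type="xs:string" use="required"/>
    <xs:attribute name="codeSystem" type="xs:string" use="required"/>
    <xs:attribute name="displayName" type="xs:string" use="required"/>
    <xs:attribute name="approximate" type="xs:boolean" use="optional"/>
  </xs:complexType>

  <xs:complexType name="RelatedConcept">
    <xs:complexContent>
      <xs:extension base="po:CodedConcept">
        <xs:attribute name="relationship" use="required">
          <xs:simpleType>
            <xs:restriction base="xs:string">
              <xs:enumeration value="HAS-TARGET"/>
              <xs:enumeration value="IS-QUALIFIER-OF"/>
            </xs:restriction>
          </xs:simpleType>
        </xs:attribute>
        <xs:attribute name="ref" type="xs:IDREF" use="required"/>
      </xs:extension>
    </xs:complexContent>
  </xs:complexType>

  <xs:element name="genericObservation">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="locator" type="po:CodedConcept" minOccurs="0"/>
        <xs:element name="problemOrganizer" type="po:CodedConcept" minOccurs="0"/>
        <xs:element name="target">
          <xs:complexType>
            <xs:complexContent>
              <xs:extension base="po:CodedConcept">
                <xs:attribute name="id" type="xs:ID" use="required"/>
              </xs:extension>
            </xs:complexContent>
          </xs:complexType>
        </xs:element>
        <xs:element name="property" type="po:RelatedConcept"/>
        <xs:element name="qualifier" type="po:RelatedConcept"
                    minOccurs="0" maxOccurs="unbounded"/>
        <xs:element name="method" type="po:RelatedConcept" minOccurs="0"/>
        <xs:element name="value" minOccurs="0">
          <xs:complexType>
            <xs:choice>
              <xs:element name="code" type="po:CodedConcept"/>
              <xs:element name="quantity">
                <xs:complexType>
                  <xs:attribute name="value" type="xs:double" use="required"/>
                  <xs:attribute name="unit" type="xs:string" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:choice>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
    </xs:complexType>
  </xs:element>
</xs:schema>
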