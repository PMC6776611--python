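<?xml version='1.0' encoding='utf-8'?>
<odML version="1.3">
  <author>Alice</author>
  <date>2000-01-01</date>
  <section>
    <name>Subject</name>
    <type>subject</type>
    <section>
      <name>Scores_2000-01-01</name>
      <type>scores</type>
      <property>
        <name>Date</name>
        <value type="date">2000-01-01</value>
      </property>
      <property>
        <name>Weight</name>
        <value type="float" unit="g">5.0</value>
        <value type="float" unit="g">5.1</value>
      </property>
      <property>
        <name>Experimenter</name>
        <value type="string">Alice</value>
      </property>
    </section>
  </section>
</odML>
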